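"""Block matching, sub-pixel refinement, LOI tracking, L-maps, displacement
integration and shunt correction."""

import numpy as np
import pytest

import stmotility as sm
from stmotility.tracking import _integer_argmin

from conftest import fourier_shift


def naive_match(P, Q, center, h, s, metric="mean_removed_ssd"):
    """Independent double-loop evaluation of the matching function."""
    r, c = center
    out = np.empty((2 * s + 1, 2 * s + 1))
    pwin = P[r - h:r + h + 1, c - h:c + h + 1]
    mu_p = pwin.mean()
    for a, x in enumerate(range(-s, s + 1)):
        for b, y in enumerate(range(-s, s + 1)):
            qwin = Q[r + x - h:r + x + h + 1, c + y - h:c + y + h + 1]
            mu_q = qwin.mean()
            if metric == "mean_removed_ssd":
                acc = 0.0
                for i in range(2 * h + 1):
                    for j in range(2 * h + 1):
                        acc += ((pwin[i, j] - mu_p) - (qwin[i, j] - mu_q)) ** 2
            else:
                acc = np.abs(pwin - qwin).sum()
            out[a, b] = acc
    return out


class TestMatchWindow:
    def test_identity_minimum_at_zero(self, speckle_image):
        surf = sm.match_window(speckle_image, speckle_image, (48, 64),
                               sm.MatchConfig(window_half=10, search_range=5))
        assert surf.values[5, 5] == pytest.approx(0.0, abs=1e-18)
        assert surf.values.min() == surf.values[5, 5]

    def test_integer_shift_recovered(self, speckle_image):
        q = np.roll(speckle_image, (3, -2), axis=(0, 1))
        surf = sm.match_window(speckle_image, q, (48, 64),
                               sm.MatchConfig(window_half=10, search_range=5))
        ia, ib = np.unravel_index(np.argmin(surf.values), surf.values.shape)
        assert (surf.row_shifts[ia], surf.col_shifts[ib]) == (3, -2)

    def test_default_surface_is_31x31(self, speckle_image):
        surf = sm.match_window(speckle_image, speckle_image, (48, 64))
        assert surf.values.shape == (31, 31)

    @pytest.mark.parametrize("metric", ["mean_removed_ssd", "sad"])
    def test_agrees_with_naive_double_loop(self, metric):
        """Oracle equivalence on random window pairs."""
        rng = np.random.default_rng(1)
        h, s = 5, 3
        for _ in range(8):
            P = rng.random((40, 40))
            Q = rng.random((40, 40))
            surf = sm.match_window(P, Q, (20, 20),
                                   sm.MatchConfig(window_half=h, search_range=s,
                                                  metric=metric))
            expected = naive_match(P, Q, (20, 20), h, s, metric)
            assert np.abs(surf.values - expected).max() < 1e-9

    def test_flat_window_raises(self):
        flat = np.full((60, 60), 9.0)
        with pytest.raises(ValueError, match="flat"):
            sm.match_window(flat, flat, (30, 30),
                            sm.MatchConfig(window_half=5, search_range=3))

    def test_border_window_raises(self, speckle_image):
        with pytest.raises(ValueError, match="fit"):
            sm.match_window(speckle_image, speckle_image, (5, 5))


class TestSubpixelMinimum:
    def test_symmetric_surface_returns_node(self):
        s = 4
        shifts = np.arange(-s, s + 1)
        vals = shifts[:, None] ** 2 + shifts[None, :] ** 2 + 1.0
        surf = sm.CorrelationSurface(vals.astype(float), shifts, shifts.copy(),
                                     0.0, np.zeros_like(vals, dtype=float), 1.0)
        d = sm.subpixel_minimum(surf)
        assert (d.d_row, d.d_col) == (0.0, 0.0)

    def test_quadratic_bowl_center_recovered(self):
        s = 4
        shifts = np.arange(-s, s + 1, dtype=float)
        yy, xx = np.meshgrid(shifts, shifts, indexing="ij")
        vals = (yy - 1.4) ** 2 + (xx + 0.6) ** 2 + 2.0
        surf = sm.CorrelationSurface(vals, shifts, shifts.copy(), 0.0,
                                     np.zeros_like(vals), 1.0)
        d = sm.subpixel_minimum(surf)
        assert d.d_row == pytest.approx(1.4, abs=0.05)
        assert d.d_col == pytest.approx(-0.6, abs=0.05)

    def test_speckle_half_pixel_shift(self, speckle_image):
        q = fourier_shift(speckle_image, 0.0, 0.5)
        d = sm.track_point(speckle_image, q, (48, 64),
                           sm.MatchConfig(window_half=10, search_range=4))
        assert d.d_col == pytest.approx(0.5, abs=0.1)
        assert d.d_row == pytest.approx(0.0, abs=0.1)

    def test_spline_minimum_matches_dense_grid_search(self, speckle_image):
        """The numerical spline minimum agrees with a 0.01-px brute-force
        evaluation of the same interpolant."""
        from scipy.interpolate import RectBivariateSpline

        q = fourier_shift(speckle_image, 0.3, -0.7)
        cfg = sm.MatchConfig(window_half=10, search_range=4)
        surf = sm.match_window(speckle_image, q, (48, 64), cfg)
        d = sm.subpixel_minimum(surf, cfg)
        spl = RectBivariateSpline(surf.row_shifts, surf.col_shifts,
                                  surf.values, kx=3, ky=3)
        ia, ib = _integer_argmin(surf)
        g = np.arange(-1, 1.0001, 0.01)
        gy = surf.row_shifts[ia] + g
        gx = surf.col_shifts[ib] + g
        dense = spl(gy, gx)
        i, j = np.unravel_index(np.argmin(dense), dense.shape)
        assert d.d_row == pytest.approx(gy[i], abs=0.02)
        assert d.d_col == pytest.approx(gx[j], abs=0.02)

    def test_border_minimum_flagged(self, speckle_image):
        q = np.roll(speckle_image, 6, axis=1)
        surf = sm.match_window(speckle_image, q, (48, 64),
                               sm.MatchConfig(window_half=10, search_range=4))
        d = sm.subpixel_minimum(surf)
        assert not d.valid

    def test_tie_break_prefers_no_motion(self):
        s = 2
        shifts = np.arange(-s, s + 1)
        vals = np.ones((5, 5))
        surf = sm.CorrelationSurface(vals, shifts, shifts.copy(), 0.0,
                                     np.zeros_like(vals, dtype=float), 1.0)
        assert _integer_argmin(surf) == (2, 2)


class TestTranslationCovariance:
    @pytest.mark.parametrize("shift", [0.25, 0.5, 1.75, 3.5])
    def test_subpixel_shifts_recovered(self, speckle_image, shift):
        q = fourier_shift(speckle_image, 0.0, shift)
        d = sm.track_point(speckle_image, q, (48, 64),
                           sm.MatchConfig(window_half=10, search_range=6))
        assert abs(d.d_col - shift) < 0.1


class TestTrackLoi:
    def test_static_video_zero_velocity(self, marker_texture):
        stack = sm.FrameStack(np.repeat(marker_texture[None], 4, axis=0), 1 / 15)
        loi = sm.LineOfInterest.horizontal(50, 25, 195)
        tr = sm.track_loi(stack, loi, sm.MatchConfig(window_half=10,
                                                     search_range=3))
        assert np.nanmax(np.abs(tr["velocity"])) < 0.02

    def test_rigid_translation_velocity(self, marker_texture):
        frames = np.stack([np.roll(marker_texture, 3 * k, axis=1)
                           for k in range(5)])
        stack = sm.FrameStack(frames, 1 / 15)
        loi = sm.LineOfInterest.horizontal(50, 25, 180)
        tr = sm.track_loi(stack, loi, sm.MatchConfig(window_half=10,
                                                     search_range=4))
        v = tr["velocity"][tr["valid"]]
        np.testing.assert_allclose(v, 45.0, rtol=0.02)

    def test_pendular_velocity_matches_ground_truth(self):
        scene = sm.TubeScene(length_px=220, n_frames=16, seed=9, noise_sd=1.0)
        prog = sm.ContractionProgram(pattern="pendular", amplitude=0.0,
                                     temporal_frequency=0.5,
                                     prescribed_strain_amplitude=0.08)
        stack, gt = sm.simulate_tube(scene, prog)
        loi = sm.LineOfInterest.horizontal(scene.centerline_row, 20, 200)
        tr = sm.track_loi(stack, loi, sm.MatchConfig(window_half=10,
                                                     search_range=4))
        # ground-truth pair-interval mean velocity at the LOI samples
        u = gt.longitudinal_displacement
        cols = loi.points[:, 1].astype(int)
        v_true = (u[1:, cols] - u[:-1, cols]) / scene.frame_interval_s
        v = tr["velocity"]
        ok = np.isfinite(v)
        amp = np.abs(v_true).max()
        rms = np.sqrt(np.mean((v[ok] - v_true[ok]) ** 2))
        assert rms < 0.05 * amp


class TestLmap:
    def test_rigid_translation_zero_strain(self, marker_texture):
        frames = np.stack([np.roll(marker_texture, 3 * k, axis=1)
                           for k in range(5)])
        stack = sm.FrameStack(frames, 1 / 15)
        loi = sm.LineOfInterest.horizontal(50, 25, 180)
        tr = sm.track_loi(stack, loi, sm.MatchConfig(window_half=10,
                                                     search_range=4))
        lmap = sm.build_lmap(tr)
        assert np.nanmax(np.abs(lmap.values)) < 0.2
        assert lmap.units == "%/s"

    def test_uniform_strain_rate_recovered(self):
        scene = sm.TubeScene(length_px=256, n_frames=10, seed=10, noise_sd=1.0)
        prog = sm.ContractionProgram(amplitude=0.0,
                                     longitudinal_coupling="prescribed",
                                     prescribed_strain_amplitude=-0.03)
        stack, _ = sm.simulate_tube(scene, prog)
        loi = sm.LineOfInterest.horizontal(scene.centerline_row, 30, 225)
        tr = sm.track_loi(stack, loi, sm.MatchConfig(window_half=10,
                                                     search_range=4))
        lmap = sm.build_lmap(tr)
        assert np.nanmean(lmap.values) == pytest.approx(-3.0, rel=0.1)

    def test_strain_additivity(self):
        """The integral of the L-map over an interval equals the rate of
        change of the distance between the interval's end markers."""
        scene = sm.TubeScene(length_px=256, n_frames=10, seed=12, noise_sd=1.0)
        prog = sm.ContractionProgram(amplitude=0.0,
                                     longitudinal_coupling="prescribed",
                                     prescribed_strain_amplitude=-0.03)
        stack, gt = sm.simulate_tube(scene, prog)
        loi = sm.LineOfInterest.horizontal(scene.centerline_row, 30, 225)
        tr = sm.track_loi(stack, loi, sm.MatchConfig(window_half=10,
                                                     search_range=4))
        lmap = sm.build_lmap(tr)
        a, b = 20, 170  # sample indices along the LOI
        integral = np.nansum(lmap.values[0, a:b]) / 100.0  # px/s
        cols = loi.points[[a, b], 1].astype(int)
        u = gt.longitudinal_displacement
        d0 = (cols[1] + u[0, cols[1]]) - (cols[0] + u[0, cols[0]])
        d1 = (cols[1] + u[1, cols[1]]) - (cols[0] + u[1, cols[0]])
        rate_true = (d1 - d0) / scene.frame_interval_s
        assert integral == pytest.approx(rate_true, rel=0.02)


class TestIntegrateDisplacement:
    def _tracking(self, v):
        return {"velocity": v, "frame_interval_s": 1 / 15, "stride": 1}

    def test_zero_velocity(self):
        d = sm.integrate_displacement(self._tracking(np.zeros((5, 4))))
        assert np.all(d == 0) and d.shape == (6, 4)

    def test_constant_velocity(self):
        v = np.full((30, 3), 45.0)
        d = sm.integrate_displacement(self._tracking(v))
        assert d[-1, 0] == pytest.approx(45.0 * 2.0, rel=0.01)

    def test_sinusoidal_amplitude(self):
        f, v0, dt = 0.5, 30.0, 1 / 15
        t = np.arange(90) * dt
        # pair-mean velocities, as a tracker of u = -v0/(2 pi f) cos would report
        u = -v0 / (2 * np.pi * f) * np.cos(2 * np.pi * f * np.append(t, t[-1] + dt))
        v = np.diff(u)[:, None] / dt
        d = sm.integrate_displacement(self._tracking(v))
        amp = (d.max() - d.min()) / 2
        assert amp == pytest.approx(v0 / (2 * np.pi * f), rel=0.02)

    def test_gap_carries_last_value(self):
        v = np.full((4, 1), 15.0)
        v[2, 0] = np.nan
        d = sm.integrate_displacement(self._tracking(v))
        assert d[-1, 0] == pytest.approx(4.0)


class TestShuntCorrection:
    def test_zero_displacement_identity(self):
        vals = np.tile(np.linspace(40, 60, 50), (6, 1))
        m = sm.STMap(vals, kind="D", units="px", frame_interval_s=1 / 15)
        disp = np.zeros((7, 50))
        out = sm.correct_shunting(m, disp, np.arange(50.0))
        np.testing.assert_allclose(out.values, vals, atol=1e-9)

    def test_uniform_translation_removes_band_slope(self):
        """With u = c*t, the corrected band slope drops by exactly c."""
        n_t, n_x, dt = 40, 120, 1 / 15
        c = 12.0  # px/s bulk drift
        vals = np.empty((n_t, n_x))
        x = np.arange(n_x)
        for t in range(n_t):
            center = 30 + c * t * dt
            vals[t] = 60 - 25 * np.exp(-((x - center) ** 2) / (2 * 8.0**2))
        m = sm.STMap(vals, kind="D", units="px", frame_interval_s=dt)
        disp = (np.arange(n_t + 1)[:, None] * dt * c) * np.ones((1, n_x))
        out = sm.correct_shunting(m, disp, x.astype(float))
        centers = np.array([np.nanargmin(row) for row in out.values[:-1]])
        assert np.ptp(centers) <= 1

    def test_oscillating_bulk_motion_corrected(self, peristalsis_run=None):
        scene = sm.TubeScene(length_px=192, n_frames=31, seed=13, noise_sd=1.0)
        prog = sm.ContractionProgram(amplitude=0.5, wave_speed=0.0,
                                     temporal_frequency=0.0, spatial_extent=15.0,
                                     bulk_oscillation_px=5.0,
                                     bulk_frequency_hz=0.25)
        stack, _ = sm.simulate_tube(scene, prog)
        dmap = sm.build_dmap(stack)
        loi = sm.LineOfInterest.horizontal(scene.centerline_row, 20, 172)
        tr = sm.track_loi(stack, loi, sm.MatchConfig(window_half=10,
                                                     search_range=4))
        disp = sm.integrate_displacement(tr)
        out = sm.correct_shunting(dmap, disp, loi.points[:, 1])

        def centroid_drift(m):
            cents = []
            for row in m.values:
                ok = np.isfinite(row)
                cols = np.flatnonzero(ok).astype(float)
                depth = np.clip(np.nanmedian(row[ok]) - row[ok], 0, None)
                cents.append((cols * depth).sum() / depth.sum())
            return np.ptp(cents)

        assert centroid_drift(dmap) > 5.0
        assert centroid_drift(out) < 1.0


class TestTonicDrift:
    def test_downsampling_improves_slow_tonic_change(self):
        """Cumulative tracking of a slow tonic elongation drifts at stride 1;
        less frequent frame sampling (stride 15) recovers the elongation
        within 10%."""
        scene = sm.TubeScene(length_px=200, n_frames=151, seed=14, noise_sd=2.0)
        prog = sm.ContractionProgram(amplitude=0.0,
                                     longitudinal_coupling="prescribed",
                                     prescribed_strain_amplitude=0.0008)
        stack, gt = sm.simulate_tube(scene, prog)
        loi = sm.LineOfInterest.horizontal(scene.centerline_row, 40, 160)
        cfg = sm.MatchConfig(window_half=10, search_range=4)
        rel_err = {}
        for stride in (1, 15):
            tr = sm.track_loi(stack, loi, cfg, stride=stride)
            disp = sm.integrate_displacement(tr)
            measured = disp[-1, -1] - disp[-1, 0]
            row = tr["velocity"].shape[0] * stride
            u = gt.longitudinal_displacement
            cols = loi.points[[0, -1], 1].astype(int)
            true = u[row, cols[1]] - u[row, cols[0]]
            rel_err[stride] = abs(measured - true) / abs(true)
        assert rel_err[15] < 0.10
        assert rel_err[15] < rel_err[1]
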