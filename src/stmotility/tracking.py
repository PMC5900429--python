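"""Surface-marker tracking and longitudinal strain-rate (L-type) maps.

Local motion between successive frames is found with a block-matching
function: for a square window around a reference point in frame ``P`` and a
trial displacement ``(x, y)``, the match cost is the mean-removed sum of
squared differences

    C(x, y) = sum_ij ((P(i,j) - mu_P) - (Q(i+x, j+y) - mu_Q))^2

with ``mu_P``/``mu_Q`` the mean intensities of the two windows (a
sum-of-absolute-differences variant is available).  Although this family of
functions is conventionally called "cross-correlation" in the motility
literature, the quantity minimized is an SSD; the minimizer is the same
displacement a mean-removed correlation would maximize.  The integer-grid
minimum is refined to sub-pixel precision by fitting a 2-D cubic spline to
the cost surface and minimizing the spline, giving displacements in
fractions of a pixel.

Velocities sampled along a line of interest (LOI) yield the L-type ST map:
the spatial derivative of tangential velocity along arc length, in %/s,
negative where the tissue is locally shortening.  Time-integrated velocities
give displacement maps, which in turn re-address D-map columns to material
coordinates (undoing "shunting": passive lengthwise displacement of
uncontracted wall by contractions elsewhere).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, optimize, signal

from .core import SENTINEL, FrameStack, LineOfInterest, STMap

log = logging.getLogger(__name__)


@dataclass
class MatchConfig:
    """Block-matching settings: a ``(2*window_half+1)``-square window searched
    over integer displacements ``-search_range..+search_range`` in both axes.
    Defaults follow common practice for gastrointestinal preparations filmed
    at 15 fps: a 21x21 window and a +/-15 px search."""

    window_half: int = 10
    search_range: int = 15
    metric: str = "mean_removed_ssd"
    refine: str = "spline"
    quality_max: float = np.inf   # invalidate samples with quality above this

    def __post_init__(self) -> None:
        if self.window_half < 3:
            raise ValueError("window_half must be >= 3")
        if self.search_range < 1:
            raise ValueError("search_range must be >= 1")
        if self.metric not in ("mean_removed_ssd", "sad"):
            raise ValueError("metric must be 'mean_removed_ssd' or 'sad'")
        if self.refine not in ("spline", "none"):
            raise ValueError("refine must be 'spline' or 'none'")


@dataclass
class CorrelationSurface:
    """Match cost on the integer displacement grid.

    ``values[a, b]`` is the cost for a displacement of
    ``(row_shifts[a], col_shifts[b])`` pixels; ``p_mean`` is the reference
    window mean and ``q_means[a, b]`` the mean of the corresponding displaced
    window."""

    values: np.ndarray
    row_shifts: np.ndarray
    col_shifts: np.ndarray
    p_mean: float
    q_means: np.ndarray
    p_var: float
    n_window: int = 441   # pixels per matching window


@dataclass
class Displacement:
    """A sub-pixel displacement ``(d_row, d_col)`` with a match-quality score
    (minimum cost normalized by window variance; smaller is better)."""

    d_row: float
    d_col: float
    quality: float
    valid: bool = True


def match_window(p_frame: np.ndarray, q_frame: np.ndarray,
                 center: tuple[int, int], config: MatchConfig | None = None
                 ) -> CorrelationSurface:
    """Evaluate the matching function over the full integer search grid.

    ``center`` is the (row, col) of the reference point in ``p_frame``.  The
    window plus the search range must fit inside both frames; a flat
    (zero-variance) reference window raises, since no displacement is
    identifiable.
    """
    config = config or MatchConfig()
    P = np.asarray(p_frame, dtype=float)
    Q = np.asarray(q_frame, dtype=float)
    h, s = config.window_half, config.search_range
    r, c = int(center[0]), int(center[1])
    if (r - h - s < 0 or c - h - s < 0
            or r + h + s >= P.shape[0] or c + h + s >= P.shape[1]):
        raise ValueError("window plus search range does not fit inside the frame")

    pwin = P[r - h:r + h + 1, c - h:c + h + 1]
    mu_p = pwin.mean()
    p_var = pwin.var()
    if p_var == 0:
        raise ValueError("flat reference window: displacement unidentifiable")
    p_tilde = pwin - mu_p

    region = Q[r - h - s:r + h + s + 1, c - h - s:c + h + s + 1]
    wins = np.lib.stride_tricks.sliding_window_view(region, (2 * h + 1, 2 * h + 1))
    mu_q = wins.mean(axis=(2, 3))
    if config.metric == "mean_removed_ssd":
        diff = (p_tilde[None, None] - (wins - mu_q[..., None, None]))
        values = np.einsum("abij,abij->ab", diff, diff)
    else:
        values = np.abs(pwin[None, None] - wins).sum(axis=(2, 3))
    shifts = np.arange(-s, s + 1)
    return CorrelationSurface(values=values, row_shifts=shifts,
                              col_shifts=shifts.copy(), p_mean=float(mu_p),
                              q_means=mu_q, p_var=float(p_var),
                              n_window=(2 * h + 1) ** 2)


def _integer_argmin(surface: CorrelationSurface) -> tuple[int, int]:
    """Grid argmin with deterministic tie-breaking: smallest displacement
    magnitude, then smallest col shift, then smallest row shift — biased
    toward the null hypothesis of no motion."""
    v = surface.values
    m = v.min()
    ia, ib = np.nonzero(v == m)
    rs = surface.row_shifts[ia].astype(float)
    cs = surface.col_shifts[ib].astype(float)
    order = np.lexsort((rs, cs, np.hypot(rs, cs)))
    k = order[0]
    return int(ia[k]), int(ib[k])


def subpixel_minimum(surface: CorrelationSurface,
                     config: MatchConfig | None = None) -> Displacement:
    """Refine the grid minimum of the cost surface to sub-pixel precision.

    A bicubic spline interpolant of the surface is minimized numerically
    within +/-1 px of the integer argmin.  If the argmin lies on the search
    border, or the minimization fails, the integer minimum is returned
    flagged invalid.
    """
    config = config or MatchConfig()
    ia, ib = _integer_argmin(surface)
    rs, cs = surface.row_shifts, surface.col_shifts
    quality = float(surface.values[ia, ib] / max(surface.p_var, 1e-300))
    on_border = (ia == 0 or ib == 0
                 or ia == len(rs) - 1 or ib == len(cs) - 1)
    if on_border or config.refine == "none":
        return Displacement(float(rs[ia]), float(cs[ib]), quality,
                            valid=not on_border)
    # a (numerically) perfect match pins the displacement to the grid node:
    # the SSD of identical windows is 0, and spline refinement could only
    # overshoot below it
    if surface.values[ia, ib] <= 1e-12 * surface.n_window * surface.p_var:
        return Displacement(float(rs[ia]), float(cs[ib]), quality, valid=True)
    spl = interpolate.RectBivariateSpline(rs, cs, surface.values, kx=3, ky=3)
    x0 = np.array([rs[ia], cs[ib]], dtype=float)
    bounds = [(x0[0] - 1, x0[0] + 1), (x0[1] - 1, x0[1] + 1)]
    res = optimize.minimize(
        lambda z: float(spl(z[0], z[1], grid=False)), x0, bounds=bounds,
        method="L-BFGS-B")
    if not res.success:
        return Displacement(float(rs[ia]), float(cs[ib]), quality, valid=False)
    q = float(spl(res.x[0], res.x[1], grid=False) / max(surface.p_var, 1e-300))
    return Displacement(float(res.x[0]), float(res.x[1]), q, valid=True)


def track_point(p_frame: np.ndarray, q_frame: np.ndarray,
                center: tuple[int, int], config: MatchConfig | None = None
                ) -> Displacement:
    """Convenience: match then refine a single reference point."""
    config = config or MatchConfig()
    try:
        surf = match_window(p_frame, q_frame, center, config)
    except ValueError:
        return Displacement(0.0, 0.0, np.inf, valid=False)
    d = subpixel_minimum(surf, config)
    if d.quality > config.quality_max:
        d.valid = False
    return d


def track_loi(stack: FrameStack, loi: LineOfInterest,
              config: MatchConfig | None = None, stride: int = 1
              ) -> dict:
    """Track every LOI sample through the stack (material tracking).

    For each processed frame pair ``t -> t+stride`` the displacement of each
    sample is measured, projected onto the local LOI tangent and divided by
    the pair interval; the tracking window is then re-centered on the
    advected position for the next pair.  Returns a dict with keys
    ``velocity`` (tangential, px/s, shape ``(n_pairs, n_samples)``),
    ``velocity_normal`` (off-tangent diagnostic channel), ``valid``,
    ``s`` (arc-length coordinates) and ``pair_times`` (start time of each
    pair).
    """
    config = config or MatchConfig()
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = stack.frames
    idx = np.arange(0, stack.n_frames - stride, stride)
    tangents = loi.tangents()
    pos = loi.points.copy()
    dt = stride * stack.frame_interval_s

    n_pairs, n_samples = len(idx), loi.n_samples
    vel_t = np.full((n_pairs, n_samples), SENTINEL)
    vel_n = np.full((n_pairs, n_samples), SENTINEL)
    valid = np.zeros((n_pairs, n_samples), dtype=bool)

    for k, t0 in enumerate(idx):
        P, Q = frames[t0], frames[t0 + stride]
        n_bad = 0
        for j in range(n_samples):
            center = (int(round(pos[j, 0])), int(round(pos[j, 1])))
            d = track_point(P, Q, center, config)
            if not d.valid:
                n_bad += 1
                continue
            tang = tangents[j]
            v_t = (d.d_row * tang[0] + d.d_col * tang[1]) / dt
            v_n = (-d.d_row * tang[1] + d.d_col * tang[0]) / dt
            vel_t[k, j] = v_t
            vel_n[k, j] = v_n
            valid[k, j] = True
            pos[j, 0] += d.d_row
            pos[j, 1] += d.d_col
        if n_bad > 0.3 * n_samples:
            log.warning("frame pair %d: %d of %d LOI samples invalid",
                        t0, n_bad, n_samples)
    return {"velocity": vel_t, "velocity_normal": vel_n, "valid": valid,
            "s": loi.s.copy(), "pair_times": idx * stack.frame_interval_s,
            "frame_interval_s": stack.frame_interval_s, "stride": stride}


def build_lmap(tracking: dict, smooth_window: int = 5, polyorder: int = 2
               ) -> STMap:
    """L-type ST map: longitudinal strain rate (%/s) along the LOI.

    The strain rate is the arc-length derivative of tangential velocity,
    computed with a Savitzky-Golay derivative filter (local quadratic
    smoothing over ``smooth_window`` samples, central differences built in)
    and scaled to percent per second.  Negative values mark local shortening
    (active contraction or recovery after stretch); positive values mark
    lengthening.
    """
    v = np.asarray(tracking["velocity"], dtype=float)
    if smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    n_pairs, n_samples = v.shape
    out = np.full_like(v, SENTINEL)
    for k in range(n_pairs):
        row = v[k]
        ok = np.isfinite(row)
        if ok.sum() < 2:
            continue
        filled = row.copy()
        if not ok.all():  # bridge gaps for filtering, re-mask afterwards
            filled[~ok] = np.interp(np.flatnonzero(~ok), np.flatnonzero(ok),
                                    row[ok])
        win = min(smooth_window, n_samples if n_samples % 2 else n_samples - 1)
        if win <= polyorder:
            deriv = np.gradient(filled)
        else:
            deriv = signal.savgol_filter(filled, win, polyorder, deriv=1,
                                         delta=1.0)
        deriv[~ok] = SENTINEL
        out[k] = deriv * 100.0
    return STMap(out, kind="L", units="%/s",
                 frame_interval_s=tracking["frame_interval_s"],
                 stride=tracking["stride"], origin="arc length s=0 of the LOI")


def integrate_displacement(tracking: dict) -> np.ndarray:
    """Cumulative time-integral of tangential velocity (px).

    Each tracked velocity sample is the measured displacement over one
    frame-pair interval divided by that interval, so ``v * dt`` is already
    the exact integral of velocity over the pair; the cumulative sum of these
    increments is therefore the trapezoid-exact displacement at the pair
    boundaries.  Row 0 is zero; row ``k`` is the displacement at the start of
    pair ``k`` (shape ``(n_pairs + 1, n_samples)``).  Gaps (invalid samples)
    carry the last valid velocity forward and are logged.
    """
    v = np.asarray(tracking["velocity"], dtype=float).copy()
    dt = tracking["stride"] * tracking["frame_interval_s"]
    n_pairs, n_samples = v.shape
    if np.isnan(v).any():
        log.warning("invalid velocity samples: carrying last valid value")
        for j in range(n_samples):
            col = v[:, j]
            ok = np.isfinite(col)
            if not ok.any():
                v[:, j] = 0.0
                continue
            last = 0.0
            for k in range(n_pairs):
                if ok[k]:
                    last = col[k]
                else:
                    v[k, j] = last
    disp = np.zeros((n_pairs + 1, n_samples))
    disp[1:] = np.cumsum(v * dt, axis=0)
    return disp


def correct_shunting(dmap: STMap, displacement: np.ndarray,
                     sample_columns: np.ndarray) -> STMap:
    """Re-address D-map columns to material coordinates.

    ``displacement[t, j]`` is the lab displacement (px, along the map axis)
    of the material point whose reference position is ``sample_columns[j]``
    (typically the LOI samples of the tracking run that produced it).  Each
    D-map row is resampled by linear interpolation so that output column
    ``xi`` holds the diameter at lab position ``xi + u(xi, t)`` — the column
    then follows a fixed tissue point instead of a fixed frame column.
    Columns where the lab mapping folds over (non-monotonic ``x + u``) are
    flagged invalid.
    """
    displacement = np.asarray(displacement, dtype=float)
    u_rows = displacement.shape[0]
    if u_rows < dmap.n_rows - 1:
        raise ValueError("displacement does not cover the D-map time base")
    if u_rows < dmap.n_rows:  # tracking yields one fewer boundary than frames
        displacement = np.vstack([displacement, displacement[-1]])
    cols = np.arange(dmap.n_cols, dtype=float)
    out = np.full_like(dmap.values, SENTINEL)
    sc = np.asarray(sample_columns, dtype=float)
    for t in range(dmap.n_rows):
        u = np.interp(cols, sc, displacement[t])
        lab = cols + u
        row = dmap.values[t]
        ok = np.isfinite(row)
        if ok.sum() < 2:
            continue
        sampled = np.interp(lab, cols[ok], row[ok], left=np.nan, right=np.nan)
        if np.any(np.diff(lab) <= 0):
            bad = np.zeros_like(lab, dtype=bool)
            bad[1:] |= np.diff(lab) <= 0
            bad[:-1] |= np.diff(lab) <= 0
            sampled[bad] = SENTINEL
        out[t] = sampled
    return dmap.copy_with(values=out, kind="D", origin=dmap.origin +
                          " (material coordinates, shunt-corrected)")
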