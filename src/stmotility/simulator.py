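"""Synthetic motility-video simulator with exact ground truth.

Renders a bright tubular organ (or a round sacculate organ) on a dark
background, carrying randomly scattered dark surface markers, and deforms it
under configurable contraction programs: propagating peristalsis, mass
peristalsis with asymmetric onset/offset, stationary segmentation, pendular
longitudinal oscillation, and localized contracting patches.  Every scene is
rendered from closed-form diameter and displacement fields, which are returned
alongside the frames as :class:`GroundTruth`, so each mapping stage can be
validated against the exact fields used for rendering.

Conventions: image coordinates are 0-based ``(row, col)`` with pixel centers
at integers; the tube axis runs along columns; intensities are on a 0–255
scale regardless of the eventual file bit depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FrameStack

log = logging.getLogger(__name__)

PATTERNS = ("peristalsis", "mass_peristalsis", "segmentation", "pendular", "patch")
COUPLINGS = ("none", "incompressible", "prescribed")


@dataclass
class TubeScene:
    """Geometry, texture and acquisition parameters of a tubular scene."""

    length_px: int = 256
    resting_diameter_px: float = 60.0
    centerline_row: float = 60.0
    marker_density: float = 60.0      # markers per 100x100 px of tube surface
    marker_diameter_px: float = 5.0   # blob FWHM-ish; Gaussian sigma = diameter/2
    foreground_level: float = 200.0
    background_level: float = 20.0
    noise_sd: float = 2.0
    frame_interval_s: float = 1.0 / 15.0
    n_frames: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_px < 64:
            raise ValueError("length_px must be >= 64")
        if not 0 < self.resting_diameter_px < 2 * self.centerline_row:
            raise ValueError("resting diameter must fit above/below the centerline")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.foreground_level == self.background_level:
            raise ValueError("foreground and background levels must differ")

    @property
    def height_px(self) -> int:
        return int(round(2 * self.centerline_row))


@dataclass
class ContractionProgram:
    """A contraction pattern and its kinematic parameters.

    ``amplitude`` is the fractional diameter reduction at the constriction
    peak; ``wave_speed`` the lengthwise propagation speed; ``spatial_extent``
    the Gaussian sigma of a constriction; ``longitudinal_coupling`` selects
    how lengthwise tissue motion is generated (``incompressible`` conserves
    local wall area, ``prescribed`` imposes a spatially uniform strain rate of
    ``prescribed_strain_amplitude``).  ``longitudinal_lead_s`` adds a
    traveling band of longitudinal shortening (peak strain
    ``longitudinal_strain_amplitude``) running ahead of the circular
    constriction, as seen physiologically in peristalsis.
    ``bulk_oscillation_px`` superimposes a rigid lengthwise oscillation of the
    whole preparation — the classic source of "shunting" on D-maps.
    """

    pattern: str = "peristalsis"
    amplitude: float = 0.5
    wave_speed: float = 30.0           # px / s
    temporal_frequency: float = 0.25   # Hz
    spatial_extent: float = 20.0       # px (Gaussian sigma)
    longitudinal_coupling: str = "none"
    prescribed_strain_amplitude: float = 0.0   # 1/s
    longitudinal_lead_s: float = 0.0
    longitudinal_strain_amplitude: float = 0.0
    bulk_oscillation_px: float = 0.0
    bulk_frequency_hz: float = 0.1
    hold_s: float = 1.0                # mass peristalsis: plateau before release
    rise_s: float = 0.5                # mass peristalsis: local on/off ramp time

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must be in [0, 1): full lumen closure is not modeled")
        if self.spatial_extent <= 0:
            raise ValueError("spatial_extent must be > 0")
        if self.wave_speed < 0:
            raise ValueError("wave_speed must be >= 0")
        if self.longitudinal_coupling not in COUPLINGS:
            raise ValueError(f"unknown coupling {self.longitudinal_coupling!r}")


@dataclass
class GroundTruth:
    """Exact fields used for rendering, on the (frame, column) grid.

    ``longitudinal_displacement[t, x]`` is the lab displacement of the
    material point whose resting position is column ``x``;
    ``longitudinal_strain_rate`` is its spatial-derivative rate d(du/dx)/dt in
    1/s.  ``diameter`` is in laboratory coordinates (what edge detection
    sees).  ``area_strain_rate`` is filled only by the sacculate simulator.
    """

    times: np.ndarray
    x: np.ndarray
    diameter: np.ndarray
    longitudinal_displacement: np.ndarray
    longitudinal_strain_rate: np.ndarray
    event_table: pd.DataFrame
    area_strain_rate: np.ndarray | None = None


# ---------------------------------------------------------------------------
# pattern envelopes: unit-amplitude g(x, t) and analytic dg/dt
# ---------------------------------------------------------------------------

def _envelope(program: ContractionProgram, scene_length: float,
              x: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (g, dg/dt) for one time point; g in [0, 1]."""
    p = program
    sig = p.spatial_extent
    if p.pattern == "peristalsis":
        g = np.zeros_like(x)
        dg = np.zeros_like(x)
        v = p.wave_speed
        if p.temporal_frequency > 0 and v > 0:
            # waves launched from x = 0 at regular intervals
            period = 1.0 / p.temporal_frequency
            k_max = int(np.floor((t + (scene_length + 4 * sig) / v) / period)) + 1
            for k in range(0, k_max + 1):
                c = v * (t - k * period)
                if -4 * sig < c < scene_length + 4 * sig:
                    term = np.exp(-((x - c) ** 2) / (2 * sig**2))
                    g += term
                    dg += term * (x - c) * v / sig**2
        else:
            c = scene_length / 2 if v == 0 else v * t
            term = np.exp(-((x - c) ** 2) / (2 * sig**2))
            g += term
            dg += term * (x - c) * v / sig**2
        np.clip(g, None, 1.0, out=g)
        return g, dg
    if p.pattern == "mass_peristalsis":
        # onset sweeps proximal->distal at wave_speed; after a hold the
        # release sweeps distal->proximal, giving the triangular footprint
        v = max(p.wave_speed, 1e-9)
        tau = max(p.rise_s, 1e-9)
        t_on = x / v                      # local onset time
        t_off = p.hold_s + scene_length / v + (scene_length - x) / v
        up = np.clip((t - t_on) / tau, 0.0, 1.0)
        down = np.clip((t - t_off) / tau, 0.0, 1.0)
        g = up * (1.0 - down)
        d_up = ((t > t_on) & (t < t_on + tau)) / tau
        d_down = ((t > t_off) & (t < t_off + tau)) / tau
        dg = d_up * (1.0 - down) - up * d_down
        return g, dg
    if p.pattern == "segmentation":
        lam = 4.0 * sig
        spatial = 0.5 * (1 + np.cos(2 * np.pi * (x - scene_length / 2) / lam))
        w = 2 * np.pi * p.temporal_frequency
        q = 0.5 * (1 - np.cos(w * t))
        dq = 0.5 * w * np.sin(w * t)
        return spatial * q, spatial * dq
    # pendular and patch drive no diameter change on the tube
    z = np.zeros_like(x)
    return z, z.copy()


def _longitudinal_fields(program: ContractionProgram, scene: TubeScene,
                         x: np.ndarray, t: float,
                         g: np.ndarray, dg: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Material displacement u(x, t) and strain rate d(du/dx)/dt at time t."""
    p = program
    L = float(scene.length_px)
    u = np.zeros_like(x)
    sr = np.zeros_like(x)
    A = p.amplitude

    if p.pattern == "pendular" and p.temporal_frequency > 0:
        S = p.prescribed_strain_amplitude
        w = 2 * np.pi * p.temporal_frequency
        amp = S * L / (np.pi * w) if S else 0.0
        u = u + amp * np.sin(w * t) * np.sin(np.pi * x / L)
        sr = sr + amp * w * np.cos(w * t) * (np.pi / L) * np.cos(np.pi * x / L)

    if p.longitudinal_coupling == "incompressible" and A > 0:
        # wall-area conservation: D0 dx = D dX  =>  strain = D0/D - 1
        eps = A * g / (1.0 - A * g)
        deps = A * dg / (1.0 - A * g) ** 2
        u = u + _cumtrapz(eps, x)
        sr = sr + deps
    elif p.longitudinal_coupling == "prescribed" and p.pattern != "pendular":
        S = p.prescribed_strain_amplitude
        u = u + S * t * (x - L / 2)
        sr = sr + np.full_like(x, S)

    if p.longitudinal_strain_amplitude:
        # traveling shortening band leading the constriction
        g_lead, dg_lead = _envelope(p, L, x, t + p.longitudinal_lead_s)
        eps = -p.longitudinal_strain_amplitude * g_lead
        u = u + _cumtrapz(eps, x)
        sr = sr - p.longitudinal_strain_amplitude * dg_lead

    if p.bulk_oscillation_px:
        u = u + p.bulk_oscillation_px * np.sin(2 * np.pi * p.bulk_frequency_hz * t)

    return u, sr


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(y)
    np.cumsum((y[1:] + y[:-1]) * 0.5 * np.diff(x), out=out[1:])
    return out


def _poisson_disc(rng: np.random.Generator, n: int, lo: np.ndarray,
                  hi: np.ndarray, min_dist: float, max_tries: int = 30
                  ) -> np.ndarray:
    """Dart-throwing blue-noise sampler in an axis-aligned box."""
    pts: list[np.ndarray] = []
    for _ in range(n * max_tries):
        if len(pts) >= n:
            break
        cand = lo + rng.random(2) * (hi - lo)
        if all(np.hypot(*(cand - q)) >= min_dist for q in pts):
            pts.append(cand)
    return np.array(pts) if pts else np.empty((0, 2))


def _render_markers(frame: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                    sigma: float, depth: float) -> None:
    """Subtract dark Gaussian blobs in-place, each in a local patch."""
    H, W = frame.shape
    half = int(np.ceil(4 * sigma))
    for r, c in zip(rows, cols):
        r0, r1 = int(np.floor(r)) - half, int(np.floor(r)) + half + 1
        c0, c1 = int(np.floor(c)) - half, int(np.floor(c)) + half + 1
        r0, r1 = max(r0, 0), min(r1, H)
        c0, c1 = max(c0, 0), min(c1, W)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = np.arange(r0, r1)[:, None] - r
        xx = np.arange(c0, c1)[None, :] - c
        frame[r0:r1, c0:c1] -= depth * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))


def simulate_tube(scene: TubeScene, program: ContractionProgram
                  ) -> tuple[FrameStack, GroundTruth]:
    """Render a deforming tube and return the frames plus exact ground truth.

    The diameter field is ``D(x, t) = D0 * (1 - A * g(x, t))`` with ``g`` the
    pattern's unit-amplitude envelope evaluated in material coordinates;
    surface markers are advected by the longitudinal displacement field and
    scaled radially with the local diameter.  Identical inputs (including the
    seed) produce bit-identical frame stacks.
    """
    rng = np.random.default_rng(scene.seed)
    L, H, W = scene.length_px, scene.height_px, scene.length_px
    D0 = scene.resting_diameter_px
    cl = scene.centerline_row
    x = np.arange(W, dtype=float)
    rows_col = np.arange(H, dtype=float)[:, None]
    times = np.arange(scene.n_frames) * scene.frame_interval_s

    sigma_m = scene.marker_diameter_px / 2.0
    n_markers = int(round(scene.marker_density * (L * D0) / 1e4))
    margin = 2 * sigma_m + 1
    if n_markers > 0:
        min_dist = 0.55 * np.sqrt(L * max(D0 - 2 * margin, 1) / max(n_markers, 1))
        markers = _poisson_disc(
            rng, n_markers,
            np.array([cl - D0 / 2 + margin, margin]),
            np.array([cl + D0 / 2 - margin, L - margin]),
            min_dist,
        )
    else:
        markers = np.empty((0, 2))
    if len(markers) < 4 and scene.marker_density > 0:
        log.warning("marker density too low for reliable tracking (%d markers)",
                    len(markers))
    contrast = scene.foreground_level - scene.background_level
    depth = 0.6 * abs(contrast)

    frames = np.empty((scene.n_frames, H, W))
    diam = np.empty((scene.n_frames, W))
    disp = np.empty((scene.n_frames, W))
    srate = np.empty((scene.n_frames, W))

    for ti, t in enumerate(times):
        g, dg = _envelope(program, L, x, t)
        u, sr = _longitudinal_fields(program, scene, x, t, g, dg)
        D_mat = D0 * (1.0 - program.amplitude * g)
        # lab-frame diameter: material point x sits at x + u(x, t)
        X_lab = x + u
        if np.all(np.diff(X_lab) > 0):
            D_lab = np.interp(x, X_lab, D_mat)
        else:  # fold-over: fall back to material field
            D_lab = D_mat
        cov = np.clip(D_lab[None, :] / 2 - np.abs(rows_col - cl) + 0.5, 0.0, 1.0)
        frame = scene.background_level + contrast * cov

        if len(markers):
            m_rows, m_cols = markers[:, 0], markers[:, 1]
            mu = np.interp(m_cols, x, u)
            m_cols_t = m_cols + mu
            D_here = np.interp(m_cols_t, x, D_lab)
            m_rows_t = cl + (m_rows - cl) * (D_here / D0)
            _render_markers(frame, m_rows_t, m_cols_t, sigma_m, depth)

        if scene.noise_sd > 0:
            frame += rng.normal(0.0, scene.noise_sd, frame.shape)
        np.clip(frame, 0.0, 255.0, out=frame)
        frames[ti] = frame
        diam[ti] = D_lab
        disp[ti] = u
        srate[ti] = sr

    events = _tube_event_table(program, scene)
    gt = GroundTruth(times=times, x=x, diameter=diam,
                     longitudinal_displacement=disp,
                     longitudinal_strain_rate=srate, event_table=events)
    return FrameStack(frames, scene.frame_interval_s), gt


def _tube_event_table(program: ContractionProgram, scene: TubeScene) -> pd.DataFrame:
    rows = []
    p = program
    T = scene.n_frames * scene.frame_interval_s
    if p.pattern == "peristalsis" and p.amplitude > 0:
        if p.temporal_frequency > 0 and p.wave_speed > 0:
            period = 1.0 / p.temporal_frequency
            k = 0
            while k * period < T:
                rows.append((k * period, p.wave_speed, p.temporal_frequency,
                             p.amplitude))
                k += 1
        else:
            rows.append((0.0, p.wave_speed, p.temporal_frequency, p.amplitude))
    elif p.pattern == "mass_peristalsis" and p.amplitude > 0:
        rows.append((0.0, p.wave_speed, 0.0, p.amplitude))
    return pd.DataFrame(rows, columns=["onset_s", "velocity_px_s",
                                       "frequency_hz", "amplitude_fraction"])


# ---------------------------------------------------------------------------
# sacculate organ with contracting patches
# ---------------------------------------------------------------------------

@dataclass
class SacculateScene:
    """A round organ silhouette bearing surface markers."""

    radius_px: float = 90.0
    size_px: int = 220
    marker_density: float = 14.0
    marker_diameter_px: float = 5.0
    foreground_level: float = 200.0
    background_level: float = 20.0
    noise_sd: float = 2.0
    frame_interval_s: float = 1.0 / 15.0
    n_frames: int = 60
    seed: int = 0

    @property
    def center(self) -> tuple[float, float]:
        return (self.size_px / 2.0, self.size_px / 2.0)


@dataclass
class PatchSpec:
    """One contracting patch: tissue within ``radius_px`` of ``center``
    contracts isotropically at ``area_strain_rate`` (1/s, negative =
    contraction) whenever the patch is active.  ``duty_cycle`` of the
    ``period_s`` cycle is active (active first); ``velocity_px_s`` translates
    the patch center.  ``rolloff_px`` is a cosine taper outside the uniform
    core."""

    center: tuple[float, float]
    radius_px: float
    area_strain_rate: float = -0.06
    duty_cycle: float = 1.0
    period_s: float = 4.0
    velocity_px_s: tuple[float, float] = (0.0, 0.0)
    rolloff_px: float = 6.0


def _patch_weight(r: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """1 inside the core, cosine taper to 0 over the rolloff annulus."""
    w = np.zeros_like(r)
    core = spec.radius_px
    w[r <= core] = 1.0
    ramp = (r > core) & (r < core + spec.rolloff_px)
    w[ramp] = 0.5 * (1 + np.cos(np.pi * (r[ramp] - core) / spec.rolloff_px))
    return w


def _patch_active(spec: PatchSpec, t: float) -> bool:
    if spec.duty_cycle >= 1.0:
        return True
    if spec.duty_cycle <= 0.0:
        return False
    phase = (t / spec.period_s) % 1.0
    if phase > 1.0 - 1e-9:  # guard against rounding at cycle boundaries
        phase = 0.0
    return phase < spec.duty_cycle - 1e-9


def simulate_sacculate(scene: SacculateScene, patches: list[PatchSpec]
                       ) -> tuple[FrameStack, GroundTruth]:
    """Render a sacculate organ with localized contracting patches.

    Markers inside an active patch move radially toward the patch center so
    that the local area strain rate in the patch core equals the prescribed
    value; ``GroundTruth.area_strain_rate`` holds the exact per-pixel field
    for every frame pair (row ``t`` describes the pair ``t -> t+1``).
    """
    rng = np.random.default_rng(scene.seed)
    N = scene.size_px
    R = scene.radius_px
    cr, cc = scene.center
    dt = scene.frame_interval_s
    yy, xx = np.mgrid[0:N, 0:N].astype(float)
    r_sil = np.hypot(yy - cr, xx - cc)
    silhouette = np.clip(R - r_sil + 0.5, 0.0, 1.0)

    for spec in patches:
        d = np.hypot(spec.center[0] - cr, spec.center[1] - cc)
        if d + spec.radius_px + spec.rolloff_px > R:
            log.warning("patch at %s extends outside the silhouette; clipped",
                        spec.center)

    sigma_m = scene.marker_diameter_px / 2.0
    area = np.pi * R * R
    n_markers = int(round(scene.marker_density * area / 1e4))
    min_dist = 0.55 * np.sqrt(area / max(n_markers, 1))
    # dart-throw in the bounding box, keep those inside the disc
    cand = _poisson_disc(rng, int(n_markers * 4 / np.pi) + 8,
                         np.array([cr - R + 2, cc - R + 2]),
                         np.array([cr + R - 2, cc + R - 2]), min_dist)
    if len(cand):
        inside = np.hypot(cand[:, 0] - cr, cand[:, 1] - cc) < R - 2 * sigma_m
        markers = cand[inside]
    else:
        markers = cand
    contrast = scene.foreground_level - scene.background_level
    depth = 0.6 * abs(contrast)

    frames = np.empty((scene.n_frames, N, N))
    asr = np.zeros((max(scene.n_frames - 1, 1), N, N))
    pos = markers.copy()

    for ti in range(scene.n_frames):
        t = ti * dt
        frame = scene.background_level + contrast * silhouette
        if len(pos):
            _render_markers(frame, pos[:, 0], pos[:, 1], sigma_m, depth)
        if scene.noise_sd > 0:
            frame += rng.normal(0.0, scene.noise_sd, frame.shape)
        np.clip(frame, 0.0, 255.0, out=frame)
        frames[ti] = frame

        if ti >= scene.n_frames - 1:
            break
        # advect markers into the next frame; accumulate the exact field
        for spec in patches:
            if not _patch_active(spec, t):
                continue
            pc = np.array(spec.center) + np.array(spec.velocity_px_s) * t
            lam = np.sqrt(max(1.0 + spec.area_strain_rate * dt, 0.0))
            if len(pos):
                d = pos - pc
                rr = np.hypot(d[:, 0], d[:, 1])
                w = _patch_weight(rr, spec)
                pos = pc + d * (1.0 + (lam - 1.0) * w)[:, None]
            r_pix = np.hypot(yy - pc[0], xx - pc[1])
            w_pix = _patch_weight(r_pix, spec)
            dwdr = np.zeros_like(r_pix)
            ramp = (r_pix > spec.radius_px) & (r_pix < spec.radius_px + spec.rolloff_px)
            dwdr[ramp] = -0.5 * np.pi / spec.rolloff_px * np.sin(
                np.pi * (r_pix[ramp] - spec.radius_px) / spec.rolloff_px)
            scale = 1.0 + (lam - 1.0) * w_pix
            dscale = scale + r_pix * (lam - 1.0) * dwdr
            asr[ti] += (dscale * scale - 1.0) / dt

    events = pd.DataFrame(
        [(0.0, float(np.hypot(*p.velocity_px_s)), 1.0 / p.period_s
          if p.duty_cycle < 1 else 0.0, -p.area_strain_rate)
         for p in patches],
        columns=["onset_s", "velocity_px_s", "frequency_hz", "amplitude_fraction"])
    times = np.arange(scene.n_frames) * dt
    x = np.arange(N, dtype=float)
    zeros = np.zeros((scene.n_frames, N))
    gt = GroundTruth(times=times, x=x, diameter=zeros + 2 * R,
                     longitudinal_displacement=zeros,
                     longitudinal_strain_rate=zeros, event_table=events,
                     area_strain_rate=asr)
    return FrameStack(frames, dt), gt
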