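"""Derived analytics on ST maps.

Transects pull single rows or columns out of a map with their physical axis
values; FFT analysis of temporal transects quantifies contraction
frequencies; per-column frequency profiles locate phase dislocations (abrupt
frequency-plateau boundaries); auto- and cross-correlograms reveal
rhythmicity and propagation (an angled correlogram ridge has the slope of
the propagating bands, so propagation speed is inversely proportional to the
band slope on the time-vertical map); map subtraction contrasts synchronous
maps; contraction events are segmented from D-type maps and summarized by
onset, duration, extent, velocity and amplitude; and phase offsets between
synchronous transects are measured at a stated common frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import SENTINEL, STMap


# ---------------------------------------------------------------------------
# transects
# ---------------------------------------------------------------------------

def temporal_transect(stmap: STMap, position: int) -> tuple[np.ndarray, np.ndarray]:
    """Extract the time series of one map column: ``(times_s, values)``."""
    if not 0 <= position < stmap.n_cols:
        raise IndexError(f"position {position} out of range")
    return stmap.times(), stmap.values[:, position].copy()


def spatial_transect(stmap: STMap, time_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Extract one map row: ``(positions, values)``."""
    if not 0 <= time_index < stmap.n_rows:
        raise IndexError(f"time index {time_index} out of range")
    return stmap.positions(), stmap.values[time_index].copy()


# ---------------------------------------------------------------------------
# frequency analysis
# ---------------------------------------------------------------------------

def dominant_frequency(series: np.ndarray, sample_interval_s: float,
                       detrend: bool = True
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """Dominant non-DC frequency of a uniformly sampled series.

    Returns ``(freq_hz, freqs, power)``.  ``freq_hz`` is NaN when no non-DC
    peak exists (e.g. a constant series).  Frequency resolution is
    ``1/(N*dt)``.
    """
    y = np.asarray(series, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 16:
        raise ValueError("need at least 16 finite samples")
    y = y.copy()
    if not ok.all():
        y[~ok] = np.interp(np.flatnonzero(~ok), np.flatnonzero(ok), y[ok])
    if detrend:
        y = y - y.mean()
    spec = np.fft.rfft(y)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(len(y), d=sample_interval_s)
    if len(power) < 2 or power[1:].max() <= 1e-12 * max(power[0], 1e-300):
        return float("nan"), freqs, power
    k = 1 + int(np.argmax(power[1:]))
    return float(freqs[k]), freqs, power


def frequency_map(stmap: STMap, min_rows: int = 16
                  ) -> tuple[np.ndarray, list[int]]:
    """Per-column dominant frequency profile plus candidate dislocations.

    Returns ``(profile_hz, boundaries)`` where ``boundaries`` are column
    indices at which the profile steps by more than one FFT bin — candidate
    phase-dislocation sites (fusion/bifurcation points of propagating
    bands).
    """
    if stmap.n_rows < min_rows:
        raise ValueError(f"map must have >= {min_rows} rows")
    dt = stmap.row_interval_s
    profile = np.full(stmap.n_cols, SENTINEL)
    for c in range(stmap.n_cols):
        col = stmap.values[:, c]
        if np.isfinite(col).sum() < min_rows:
            continue
        f, _, _ = dominant_frequency(col, dt)
        profile[c] = f
    bin_hz = 1.0 / (stmap.n_rows * dt)
    boundaries: list[int] = []
    ok = np.isfinite(profile)
    idx = np.flatnonzero(ok)
    for a, b in zip(idx[:-1], idx[1:]):
        if abs(profile[b] - profile[a]) > 1.5 * bin_hz:
            boundaries.append(int(b))
    return profile, boundaries


# ---------------------------------------------------------------------------
# correlograms
# ---------------------------------------------------------------------------

@dataclass
class Correlogram:
    """Normalized correlation over a (time lag, space lag) grid; the zero-lag
    cell sits at the grid center."""

    values: np.ndarray
    time_lags: np.ndarray
    space_lags: np.ndarray


def _lag_correlation(a: np.ndarray, b: np.ndarray, dt: int, dx: int) -> float:
    """Pearson correlation of the overlap of ``a`` and ``b`` shifted by
    (dt, dx), computed by direct summation over valid cells."""
    T, X = a.shape
    t0a, t1a = max(0, dt), min(T, T + dt)
    x0a, x1a = max(0, dx), min(X, X + dx)
    sub_a = a[t0a:t1a, x0a:x1a]
    sub_b = b[t0a - dt:t1a - dt, x0a - dx:x1a - dx]
    ok = np.isfinite(sub_a) & np.isfinite(sub_b)
    n = ok.sum()
    if n < 2:
        return np.nan
    av, bv = sub_a[ok], sub_b[ok]
    am, bm = av.mean(), bv.mean()
    sa = np.sqrt(((av - am) ** 2).sum())
    sb = np.sqrt(((bv - bm) ** 2).sum())
    if sa == 0 or sb == 0:
        raise ValueError("degenerate (zero-variance) overlap in correlogram")
    return float(((av - am) * (bv - bm)).sum() / (sa * sb))


def cross_correlogram(map_a: STMap, map_b: STMap, max_time_lag: int,
                      max_space_lag: int) -> Correlogram:
    """Normalized cross-correlogram of two congruent maps over the lag grid."""
    if not map_a.congruent_with(map_b):
        raise ValueError("maps are not congruent")
    a, b = map_a.values, map_b.values
    tl = np.arange(-max_time_lag, max_time_lag + 1)
    xl = np.arange(-max_space_lag, max_space_lag + 1)
    out = np.empty((len(tl), len(xl)))
    for i, dt in enumerate(tl):
        for j, dx in enumerate(xl):
            out[i, j] = _lag_correlation(a, b, int(dt), int(dx))
    np.clip(out, -1.0, 1.0, out=out)
    return Correlogram(values=out, time_lags=tl, space_lags=xl)


def autocorrelogram(stmap: STMap, max_time_lag: int,
                    max_space_lag: int) -> Correlogram:
    """Correlogram of a map with itself; the center value is exactly 1."""
    c = cross_correlogram(stmap, stmap, max_time_lag, max_space_lag)
    c.values[max_time_lag, max_space_lag] = 1.0  # exact by definition
    return c


# ---------------------------------------------------------------------------
# map arithmetic
# ---------------------------------------------------------------------------

def subtract_maps(map_a: STMap, map_b: STMap) -> STMap:
    """Elementwise ``A - B`` of congruent, same-unit maps (NaN propagates)."""
    if map_a.units != map_b.units:
        raise ValueError(f"unit mismatch: {map_a.units!r} vs {map_b.units!r}")
    if not map_a.congruent_with(map_b):
        raise ValueError("maps are not congruent")
    return map_a.copy_with(values=map_a.values - map_b.values, kind="derived",
                           origin=f"difference: ({map_a.kind}) - ({map_b.kind})")


# ---------------------------------------------------------------------------
# contraction events
# ---------------------------------------------------------------------------

@dataclass
class ContractionEvent:
    """A detected propagating constriction band on a diameter-type map."""

    onset_time_s: float
    duration_s: float
    spatial_extent_px: float
    velocity_px_s: float
    amplitude_fraction: float
    ridge: np.ndarray = field(repr=False)   # (n, 2): (time_s, position)

    def as_row(self) -> dict:
        return {"onset_time_s": self.onset_time_s,
                "duration_s": self.duration_s,
                "spatial_extent_px": self.spatial_extent_px,
                "velocity_px_s": self.velocity_px_s,
                "amplitude_fraction": self.amplitude_fraction}


def events_to_frame(events: list[ContractionEvent]) -> pd.DataFrame:
    return pd.DataFrame([e.as_row() for e in events])


def detect_events(dmap: STMap, threshold_fraction: float = 0.2,
                  min_area: int = 20, baseline_window: int = 61
                  ) -> list[ContractionEvent]:
    """Segment propagating constriction bands from a D/R/arc-D map.

    Per-column baseline = rolling median over ``baseline_window`` rows (robust
    to slow tonic drift); cells below ``(1 - threshold_fraction) * baseline``
    form the constriction mask; 8-connected components of at least
    ``min_area`` cells become events.  The event ridge is the per-row
    position of the component minimum; its least-squares slope (Theil-Sen
    fallback when the straight-line fit is poor, e.g. across a bifurcation)
    gives the signed propagation velocity, positive toward increasing column
    index.  Duration is the band breadth on the time axis at the deepest
    column; extent its breadth on the distance axis; amplitude the fractional
    reduction from baseline at the deepest cell.
    """
    if dmap.kind not in ("D", "R_upper", "R_lower", "D_arc"):
        raise ValueError("event detection expects a diameter-type map")
    if dmap.n_rows < 10:
        raise ValueError("map must have at least 10 rows")
    v = dmap.values
    win = min(baseline_window, dmap.n_rows if dmap.n_rows % 2 else dmap.n_rows - 1)
    filled = np.where(np.isfinite(v), v, np.nanmedian(v))
    baseline = ndimage.median_filter(filled, size=(win, 1), mode="nearest")
    mask = np.isfinite(v) & (v < (1.0 - threshold_fraction) * baseline)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    dt = dmap.row_interval_s
    dx = dmap.column_spacing
    events: list[ContractionEvent] = []
    for k in range(1, n + 1):
        comp = labels == k
        if comp.sum() < min_area:
            continue
        rows = np.flatnonzero(comp.any(axis=1))
        ridge = np.empty((len(rows), 2))
        for i, r in enumerate(rows):
            cols_r = np.flatnonzero(comp[r])
            c_min = cols_r[np.argmin(v[r, cols_r])]
            ridge[i] = (r * dt, c_min * dx)
        # ridge points pinned at the map borders (wave entering/leaving the
        # field of view) bias the slope; drop them for the velocity fit
        interior = (ridge[:, 1] > 0) & (ridge[:, 1] < (dmap.n_cols - 1) * dx)
        fit_ridge = ridge[interior] if interior.sum() >= 2 else ridge
        if len(fit_ridge) >= 2 and np.ptp(fit_ridge[:, 0]) > 0:
            ridge_fit = fit_ridge
            slope, intercept = np.polyfit(ridge_fit[:, 0], ridge_fit[:, 1], 1)
            pred = slope * ridge_fit[:, 0] + intercept
            ss_res = ((ridge_fit[:, 1] - pred) ** 2).sum()
            ss_tot = ((ridge_fit[:, 1] - ridge_fit[:, 1].mean()) ** 2).sum()
            if ss_tot > 0 and 1 - ss_res / ss_tot < 0.8:
                slope = stats.theilslopes(ridge_fit[:, 1], ridge_fit[:, 0])[0]
            velocity = float(slope)
        else:
            velocity = 0.0
        rmin, cmin = np.unravel_index(np.argmin(np.where(comp, v, np.inf)),
                                      v.shape)
        depth_col = comp[:, cmin]
        duration = float(depth_col.sum() * dt)
        cols = np.flatnonzero(comp.any(axis=0))
        extent = float((cols[-1] - cols[0] + 1) * dx)
        base = baseline[rmin, cmin]
        amplitude = float(1.0 - v[rmin, cmin] / base) if base > 0 else np.nan
        events.append(ContractionEvent(
            onset_time_s=float(rows[0] * dt), duration_s=duration,
            spatial_extent_px=extent, velocity_px_s=velocity,
            amplitude_fraction=amplitude, ridge=ridge))
    events.sort(key=lambda e: e.onset_time_s)
    return events


# ---------------------------------------------------------------------------
# phase
# ---------------------------------------------------------------------------

def phase_offset(series_a: np.ndarray, series_b: np.ndarray,
                 frequency_hz: float, sample_interval_s: float) -> float:
    """Phase of A relative to B at a common frequency, in degrees (−180, 180].

    Uses the single Fourier component nearest the stated frequency; NaN when
    that component is not resolvable (power below 5x the median spectral
    power) in either series.  A positive value means A leads B.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must be sampled identically")
    a = a - a.mean()
    b = b - b.mean()
    fa, fb = np.fft.rfft(a), np.fft.rfft(b)
    freqs = np.fft.rfftfreq(len(a), d=sample_interval_s)
    k = int(np.argmin(np.abs(freqs - frequency_hz)))
    if k == 0:
        return float("nan")
    for spec in (fa, fb):
        power = np.abs(spec) ** 2
        if power[k] < 5.0 * np.median(power[1:]):
            return float("nan")
    ang = np.angle(fa[k]) - np.angle(fb[k])
    deg = np.rad2deg(ang)
    deg = (deg + 180.0) % 360.0 - 180.0
    if deg == -180.0:
        deg = 180.0
    return float(deg)
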