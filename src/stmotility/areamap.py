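"""Two-dimensional area-strain-rate (A-type) fields and derived summaries.

The block-matching tracker is applied on a regular grid inside a region of
interest; the lengthwise and diametric stretch ratios between frames,
``lambda_L = 1 + du_x/dx`` and ``lambda_D = 1 + du_y/dy``, are estimated
from the gradients of the tracked displacement field, and their product
gives the local area ratio.  The area strain rate is
``(lambda_L * lambda_D - 1) / dt * 100`` in %/s; negative values mark sites
of contraction, positive values relaxation.  (To first order in small
strains this equals the sum of the two linear strain rates.)

Derived summaries: alpha-blended overlays on the source frames, stacked
contraction-density plots (per-pixel percentage of sampled frame pairs in
which the strain rate fell below a contraction threshold, default −4 %/s),
per-frame patch morphometrics in the FRAGSTATS raster conventions, and the
core-area-% time series (fraction of the ROI under active contraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage

from .core import SENTINEL, FrameStack
from .tracking import MatchConfig, track_point

#: Default contraction threshold for density plots and patch metrics (%/s).
DEFAULT_THRESHOLD = -4.0


@dataclass
class AreaStrainField:
    """Area strain rate (%/s) for one frame pair, on the tracking grid and
    bilinearly upsampled to pixel resolution within the ROI."""

    grid_values: np.ndarray      # (n_grid_rows, n_grid_cols), NaN where invalid
    grid_rows: np.ndarray
    grid_cols: np.ndarray
    pixel_values: np.ndarray     # frame-sized, NaN outside the ROI
    t_start_s: float
    dt_s: float


def _roi_grid(roi: np.ndarray, spacing: int, margin: int
              ) -> tuple[np.ndarray, np.ndarray]:
    rows = np.arange(margin, roi.shape[0] - margin, spacing)
    cols = np.arange(margin, roi.shape[1] - margin, spacing)
    return rows, cols


def compute_area_strain_rate(stack: FrameStack, roi: np.ndarray,
                             config: MatchConfig | None = None,
                             grid_spacing: int = 5, stride: int = 1,
                             smooth_sigma: float = 1.0
                             ) -> list[AreaStrainField]:
    """Track a grid through the stack and return per-pair area-strain fields.

    ``roi`` is a boolean frame-sized mask; grid nodes are laid at
    ``grid_spacing`` px inside it (nodes whose tracking window leaves the
    frame are skipped).  The tracked displacement components are smoothed
    over the grid (Gaussian, ``smooth_sigma`` in grid units) before the
    stretch-ratio gradients are formed — strain is a derivative of a noisy
    measurement, and unregularized per-node differences are jitter-dominated
    when inter-frame displacements are small.  Raises if the ROI cannot hold
    a single tracking window.
    """
    config = config or MatchConfig()
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.frame_shape:
        raise ValueError("ROI mask must match the frame shape")
    margin = config.window_half + config.search_range
    rows, cols = _roi_grid(roi, grid_spacing, margin)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("ROI too small for one tracking window")
    in_roi = roi[np.ix_(rows, cols)]
    if not in_roi.any():
        raise ValueError("no grid nodes inside the ROI")

    dt = stride * stack.frame_interval_s
    fields: list[AreaStrainField] = []
    for t0 in range(0, stack.n_frames - stride, stride):
        P, Q = stack.frames[t0], stack.frames[t0 + stride]
        u_row = np.full((rows.size, cols.size), np.nan)
        u_col = np.full((rows.size, cols.size), np.nan)
        for i, r in enumerate(rows):
            for j, c in enumerate(cols):
                if not in_roi[i, j]:
                    continue
                d = track_point(P, Q, (r, c), config)
                if d.valid:
                    u_row[i, j] = d.d_row
                    u_col[i, j] = d.d_col
        # stretch ratios from displacement-field gradients
        if smooth_sigma > 0:
            u_row = _nan_gaussian(u_row, smooth_sigma)
            u_col = _nan_gaussian(u_col, smooth_sigma)
        dur_dy = _masked_gradient(u_row, axis=0) / grid_spacing
        duc_dx = _masked_gradient(u_col, axis=1) / grid_spacing
        lam_d = 1.0 + dur_dy
        lam_l = 1.0 + duc_dx
        asr = (lam_l * lam_d - 1.0) / dt * 100.0
        pixel = _upsample(asr, rows, cols, stack.frame_shape, roi)
        fields.append(AreaStrainField(grid_values=asr, grid_rows=rows,
                                      grid_cols=cols, pixel_values=pixel,
                                      t_start_s=t0 * stack.frame_interval_s,
                                      dt_s=dt))
    return fields


def _nan_gaussian(a: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that ignores NaNs (normalized convolution)."""
    ok = np.isfinite(a)
    filled = np.where(ok, a, 0.0)
    num = ndimage.gaussian_filter(filled, sigma, mode="nearest")
    den = ndimage.gaussian_filter(ok.astype(float), sigma, mode="nearest")
    out = np.full_like(filled, np.nan)
    nz = den > 1e-9
    out[nz] = num[nz] / den[nz]
    out[~ok & (den <= 1e-9)] = np.nan
    return np.where(ok | nz, out, np.nan)


def _masked_gradient(a: np.ndarray, axis: int) -> np.ndarray:
    """np.gradient that tolerates interior NaNs by one-sided differences."""
    g = np.gradient(a, axis=axis)
    if not np.isnan(a).any():
        return g
    fwd = np.diff(a, axis=axis, append=np.take(a, [-1], axis=axis))
    bwd = np.diff(a, axis=axis, prepend=np.take(a, [0], axis=axis))
    g = np.where(np.isnan(g), fwd, g)
    g = np.where(np.isnan(g), bwd, g)
    return g


def _upsample(grid: np.ndarray, rows: np.ndarray, cols: np.ndarray,
              shape: tuple[int, int], roi: np.ndarray) -> np.ndarray:
    out = np.full(shape, SENTINEL)
    ok = np.isfinite(grid)
    if ok.sum() < 4:
        return out
    filled = grid.copy()
    if not ok.all():
        # nearest-neighbour fill so the interpolant stays defined; masked after
        idx = ndimage.distance_transform_edt(~ok, return_distances=False,
                                             return_indices=True)
        filled = grid[tuple(idx)]
    itp = interpolate.RegularGridInterpolator(
        (rows.astype(float), cols.astype(float)), filled, bounds_error=False,
        fill_value=np.nan)
    rr = np.clip(np.arange(shape[0], dtype=float), rows[0], rows[-1])
    cc = np.clip(np.arange(shape[1], dtype=float), cols[0], cols[-1])
    mesh = np.meshgrid(rr, cc, indexing="ij")
    vals = itp(np.stack([m.ravel() for m in mesh], axis=-1)).reshape(shape)
    out[roi] = vals[roi]
    return out


def overlay_amap(frame: np.ndarray, field: AreaStrainField,
                 vmax: float | None = None, alpha: float = 0.55) -> np.ndarray:
    """Alpha-blend a diverging strain-rate colormap over the grayscale frame.

    Contraction (negative) renders in warm hues, relaxation (positive) in
    cool hues; the scale is symmetric about zero (+/- ``vmax``, defaulting to
    the largest absolute finite value).  Returns an 8-bit RGB image.
    """
    from matplotlib import colormaps

    frame = np.asarray(frame, dtype=float)
    if frame.shape != field.pixel_values.shape:
        raise ValueError("frame and field are not congruent")
    lo, hi = frame.min(), frame.max()
    gray = (frame - lo) / (hi - lo) if hi > lo else np.zeros_like(frame)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    v = field.pixel_values
    ok = np.isfinite(v)
    if ok.any():
        if vmax is None:
            vmax = float(np.nanmax(np.abs(v))) or 1.0
        norm = np.clip((v + vmax) / (2 * vmax), 0.0, 1.0)
        cmap = colormaps["RdBu"]  # negative (contraction) -> red end
        colored = cmap(norm)[..., :3]
        rgb[ok] = (1 - alpha) * rgb[ok] + alpha * colored[ok]
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)


@dataclass
class DensityPlot:
    """Stacked contraction-density plot: per-pixel occupancy (%) of
    sub-threshold strain rate over the sampled frame pairs."""

    occupancy: np.ndarray
    threshold: float
    stride: int
    span_s: float
    n_sampled: int


def build_density_plot(fields: list[AreaStrainField],
                       threshold: float = DEFAULT_THRESHOLD,
                       sample_stride: int = 1) -> DensityPlot:
    """Per pixel: 100 x (pairs with strain rate strictly below threshold) /
    (pairs in which the pixel was valid).  Pixels never valid carry NaN.
    ``sample_stride`` subsamples the field sequence before stacking."""
    if len(fields) < 2:
        raise ValueError("need at least 2 sampled fields")
    sampled = fields[::sample_stride]
    stackv = np.stack([f.pixel_values for f in sampled])
    valid = np.isfinite(stackv)
    hits = (stackv < threshold) & valid
    n_valid = valid.sum(axis=0)
    occ = np.full(stackv.shape[1:], SENTINEL)
    nz = n_valid > 0
    occ[nz] = 100.0 * hits.sum(axis=0)[nz] / n_valid[nz]
    span = sampled[-1].t_start_s + sampled[-1].dt_s - sampled[0].t_start_s
    return DensityPlot(occupancy=occ, threshold=threshold,
                       stride=sample_stride, span_s=span,
                       n_sampled=len(sampled))


@dataclass
class PatchStats:
    """Morphometrics of the sub-threshold (contracting) patches of a field."""

    count: int
    mean_area_px2: float
    area_cv: float
    perimeter_area_ratio: float
    shape_index: float
    fractal_dimension: float
    core_area_pct: float


_EIGHT = np.ones((3, 3), dtype=int)


def _patch_perimeter(mask: np.ndarray) -> float:
    """Boundary edge count: pixel faces adjacent to background or border."""
    per = 0
    padded = np.pad(mask, 1, constant_values=False)
    for ax in (0, 1):
        per += np.count_nonzero(np.diff(padded.astype(np.int8), axis=ax))
    return float(per)


def patch_metrics(field: AreaStrainField,
                  threshold: float = DEFAULT_THRESHOLD) -> PatchStats:
    """FRAGSTATS-style metrics of the 8-connected sub-threshold patches.

    Shape index is the square-normalized ``0.25 * perimeter / sqrt(area)``
    (1.0 for a square); the perimeter-area fractal dimension is ``2/b`` with
    ``b`` the least-squares slope of ln(area) on ln(perimeter) pooled over
    patches (NaN unless >= 2 patches of distinct size).  Core area % is the
    thresholded area as a percentage of the valid ROI area.
    """
    v = field.pixel_values
    valid = np.isfinite(v)
    if not valid.any():
        raise ValueError("field has no valid pixels")
    mask = (v < threshold) & valid
    labels, n = ndimage.label(mask, structure=_EIGHT)
    core_pct = 100.0 * mask.sum() / valid.sum()
    if n == 0:
        return PatchStats(0, np.nan, np.nan, np.nan, np.nan, np.nan, core_pct)
    areas = ndimage.sum_labels(np.ones_like(labels), labels,
                               np.arange(1, n + 1))
    perims = np.array([
        _patch_perimeter(labels == k) for k in range(1, n + 1)])
    mean_area = float(areas.mean())
    cv = float(areas.std() / mean_area) if mean_area > 0 else np.nan
    pa_ratio = float((perims / areas).mean())
    shape_idx = float((0.25 * perims / np.sqrt(areas)).mean())
    if n >= 2 and np.ptp(np.log(perims)) > 0:
        b = np.polyfit(np.log(perims), np.log(areas), 1)[0]
        pafrac = float(2.0 / b) if b != 0 else np.nan
    else:
        pafrac = np.nan
    return PatchStats(count=int(n), mean_area_px2=mean_area, area_cv=cv,
                      perimeter_area_ratio=pa_ratio, shape_index=shape_idx,
                      fractal_dimension=pafrac, core_area_pct=core_pct)


def core_area_series(fields: list[AreaStrainField],
                     threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Per-pair core area %: sub-threshold valid area / total valid ROI area."""
    out = np.empty(len(fields))
    for i, f in enumerate(fields):
        valid = np.isfinite(f.pixel_values)
        if not valid.any():
            raise ValueError(f"field {i} has an empty ROI")
        out[i] = 100.0 * ((f.pixel_values < threshold) & valid).sum() / valid.sum()
    return out
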