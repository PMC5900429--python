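"""Core containers for spatiotemporal (ST) mapping.

A *frame stack* is an ordered sequence of equal-sized grayscale frames with a
known frame interval; an *ST map* is a 2-D grid whose rows are time and whose
columns are position along some axis (a pixel column, an arc angle, or
arc-length along a line of interest).  Missing values are carried as NaN and
are never interpolated silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Sentinel for missing / invalid map cells.  NaN propagates through
#: arithmetic and serializes as an empty CSV cell.
SENTINEL = np.nan


@dataclass
class FrameStack:
    """An ordered stack of equal-sized 2-D grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Scalar intensity frames.  Any float or integer dtype; mapping code
        promotes to float64 internally.
    frame_interval_s : float
        Time between consecutive frames in seconds (default 1/15, the usual
        video rate for smooth-muscle work).
    pixel_scale_mm : float or None
        Physical size of one pixel in millimetres, if known.
    """

    frames: np.ndarray
    frame_interval_s: float = 1.0 / 15.0
    pixel_scale_mm: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (T, H, W), got shape {self.frames.shape}"
            )
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class STMap:
    """A spatiotemporal map: rows = time, columns = position.

    ``kind`` identifies the physical quantity: ``D`` (diameter, px),
    ``R_upper``/``R_lower`` (radius to a midline, px), ``D_arc`` (chord length
    along an arcuate axis, px), ``L`` (longitudinal strain rate, %/s),
    ``A_density`` (contraction occupancy, %), ``I`` (intensity), or
    ``derived``.  Missing cells hold NaN.
    """

    values: np.ndarray
    kind: str
    units: str
    frame_interval_s: float
    stride: int = 1
    column_spacing: float = 1.0
    origin: str = ""
    ambiguous: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("STMap values must be 2-D (time × position)")
        if not self.units:
            raise ValueError("units must be non-empty")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def row_interval_s(self) -> float:
        """Time between successive map rows."""
        return self.frame_interval_s * self.stride

    def times(self) -> np.ndarray:
        return np.arange(self.n_rows) * self.row_interval_s

    def positions(self) -> np.ndarray:
        return np.arange(self.n_cols) * self.column_spacing

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy_with(self, **kw) -> "STMap":
        return replace(self, **kw)

    def congruent_with(self, other: "STMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.row_interval_s, other.row_interval_s)
            and np.isclose(self.column_spacing, other.column_spacing)
        )


class LineOfInterest:
    """A polyline in image coordinates, resampled to unit arc-length spacing.

    Control points are ordered ``(row, col)`` pairs.  The resampled points are
    spaced exactly 1 px apart along the polyline and carry an arc-length
    coordinate ``s``; L- and I-maps are computed at these samples.
    """

    def __init__(self, control_points: Sequence[tuple[float, float]]):
        pts = np.asarray(control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("need >= 2 (row, col) control points")
        self.control_points = pts
        seg = np.diff(pts, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seg_len == 0):
            raise ValueError("repeated consecutive control points")
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = cum[-1]
        n = int(np.floor(total)) + 1
        s = np.arange(n, dtype=float)
        self.points = np.column_stack(
            [np.interp(s, cum, pts[:, 0]), np.interp(s, cum, pts[:, 1])]
        )
        self.s = s
        self.length = total

    @property
    def n_samples(self) -> int:
        return self.points.shape[0]

    def tangents(self) -> np.ndarray:
        """Unit tangent (d_row, d_col) at each resampled point.

        Central differences interiorly, one-sided at the ends.
        """
        t = np.gradient(self.points, axis=0)
        norm = np.hypot(t[:, 0], t[:, 1])
        norm[norm == 0] = 1.0
        return t / norm[:, None]

    @classmethod
    def horizontal(cls, row: float, col_start: float, col_stop: float) -> "LineOfInterest":
        """Convenience: a horizontal LOI at a fixed image row."""
        return cls([(row, col_start), (row, col_stop)])
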