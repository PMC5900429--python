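"""I-type ST maps: light intensity along a line of interest.

Each map row holds the frame intensities sampled (bilinearly) at the LOI
points, so passive structures — mucosal folds, transmitted-light features,
fluorescence — can be followed without any edge or marker model.  No
detrending is applied by default; an optional per-row mean subtraction helps
visualize moving features over uneven illumination.

A caveat for quantitative use: under oblique illumination the bright region
on an I-map tracks the specular highlight, not the tissue, so the apparent
propagation speed of a distension on an I-map will not in general be a true
estimate of the speed of the wall movement itself.  Check I-map speeds
against D- or L-map values where possible.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import SENTINEL, FrameStack, LineOfInterest, STMap


def build_imap(stack: FrameStack, loi: LineOfInterest, stride: int = 1,
               subtract_row_mean: bool = False) -> STMap:
    """Build the I-type map: ``value(t, s)`` = frame ``t*stride`` sampled at
    LOI arc-length ``s``.  LOI samples outside the frame carry NaN."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    H, W = stack.frame_shape
    pts = loi.points
    inside = ((pts[:, 0] >= 0) & (pts[:, 0] <= H - 1)
              & (pts[:, 1] >= 0) & (pts[:, 1] <= W - 1))
    frames = stack.frames[::stride]
    values = np.full((len(frames), loi.n_samples), SENTINEL)
    coords = [pts[inside, 0], pts[inside, 1]]
    for i, frame in enumerate(frames):
        values[i, inside] = ndimage.map_coordinates(
            np.asarray(frame, dtype=float), coords, order=1)
    if subtract_row_mean:
        values = values - np.nanmean(values, axis=1, keepdims=True)
    return STMap(values, kind="I", units="intensity",
                 frame_interval_s=stack.frame_interval_s, stride=stride,
                 origin="arc length s=0 of the LOI")
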