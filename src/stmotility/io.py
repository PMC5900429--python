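"""Readers and writers: frame stacks, ST maps, lines of interest, provenance.

Grayscale 16-bit TIFF sequences are the canonical interchange for frames;
video containers are read-only through imageio.  Maps serialize as a CSV of
values (missing cells empty) plus a JSON sidecar of all metadata, and render
to grayscale PNG; reading inverts writing losslessly for values and
metadata.
"""

from __future__ import annotations

import glob as _glob
import json
import logging
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import SENTINEL, FrameStack, LineOfInterest, STMap

log = logging.getLogger(__name__)

_IMAGE_EXTS = {".tif", ".tiff", ".png"}


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        log.warning("color input converted to luminance; color sensors "
                    "trade away spatial definition — prefer monochrome video")
        rgb = frame[..., :3].astype(float)
        return rgb @ np.array([0.2126, 0.7152, 0.0722])
    raise ValueError(f"unsupported frame shape {frame.shape}")


def read_stack(path_or_pattern: str | os.PathLike,
               frame_interval_s: float = 1.0 / 15.0,
               pixel_scale_mm: float | None = None) -> FrameStack:
    """Load a frame stack from a video file, a multi-page TIFF, or a glob of
    numbered TIFF/PNG frames (sorted lexicographically).

    Frames are converted to single-channel scalar grids; inconsistent frame
    sizes or an empty match raise.
    """
    path = str(path_or_pattern)
    frames: list[np.ndarray]
    if any(ch in path for ch in "*?["):
        files = sorted(_glob.glob(path))
        if not files:
            raise ValueError(f"no frames match {path!r}")
        frames = [_to_gray(iio.imread(f)) for f in files]
    else:
        p = Path(path)
        if not p.exists():
            raise ValueError(f"no such input: {path!r}")
        if p.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(p)
            frames = [_to_gray(f) for f in (arr if arr.ndim >= 3 else [arr])]
        elif p.suffix.lower() == ".png":
            frames = [_to_gray(iio.imread(p))]
        else:  # video container
            frames = [_to_gray(f) for f in iio.imiter(p)]
    if not frames:
        raise ValueError("zero frames read")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame sizes: {sorted(shapes)}")
    stack = np.stack([np.asarray(f, dtype=float) for f in frames])
    return FrameStack(stack, frame_interval_s=frame_interval_s,
                      pixel_scale_mm=pixel_scale_mm)


def write_stack(stack: FrameStack, out_dir: str | os.PathLike,
                prefix: str = "frame", bit_depth: int = 16) -> list[Path]:
    """Write frames as numbered grayscale TIFFs (``frame_000000.tif``...).

    Intensities on the 0–255 scale are quantized to the requested bit depth
    (16-bit scales by 257 so 255.0 maps to 65535).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bit_depth == 16:
        conv = lambda f: (np.clip(f, 0, 255) * 257.0).round().astype(np.uint16)
    elif bit_depth == 8:
        conv = lambda f: np.clip(f, 0, 255).round().astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    paths = []
    for i, frame in enumerate(stack.frames):
        p = out / f"{prefix}_{i:06d}.tif"
        tifffile.imwrite(p, conv(frame))
        paths.append(p)
    return paths


def write_map(stmap: STMap, basepath: str | os.PathLike,
              render_png: bool = True, polarity: str = "light_small",
              transpose_render: bool = False) -> dict[str, Path]:
    """Serialize a map as ``<base>.csv`` + ``<base>.json`` (+ ``<base>.png``).

    The CSV holds the raw values, row 0 = time 0 at the top, missing cells
    empty.  The PNG render maps values to gray levels, by default lighter =
    smaller value (so constrictions read as light bands); orientation and
    polarity affect only the render, never the CSV.
    """
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    csv_path = base.with_suffix(".csv")
    pd.DataFrame(stmap.values).to_csv(csv_path, header=False, index=False,
                                      na_rep="")
    meta = {
        "kind": stmap.kind,
        "units": stmap.units,
        "frame_interval_s": stmap.frame_interval_s,
        "stride": stmap.stride,
        "column_spacing": stmap.column_spacing,
        "origin": stmap.origin,
        "shape": list(stmap.values.shape),
    }
    json_path = base.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=2))
    out = {"csv": csv_path, "json": json_path}
    if render_png:
        png_path = base.with_suffix(".png")
        iio.imwrite(png_path, render_map(stmap, polarity=polarity,
                                         transpose=transpose_render))
        out["png"] = png_path
    return out


def render_map(stmap: STMap, polarity: str = "light_small",
               transpose: bool = False) -> np.ndarray:
    """Render map values to an 8-bit grayscale image (NaN renders mid-gray)."""
    v = stmap.values
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi > lo:
        norm = (v - lo) / (hi - lo)
    else:
        norm = np.zeros_like(v)
    if polarity == "light_small":
        norm = 1.0 - norm
    elif polarity != "light_large":
        raise ValueError("polarity must be 'light_small' or 'light_large'")
    norm = np.where(np.isfinite(norm), norm, 0.5)
    img = (norm * 255).round().astype(np.uint8)
    return img.T if transpose else img


def read_map(basepath: str | os.PathLike) -> STMap:
    """Inverse of :func:`write_map` (values to full float precision)."""
    base = Path(basepath)
    json_path = base.with_suffix(".json")
    if not json_path.exists():
        raise ValueError(f"missing sidecar {json_path}")
    meta = json.loads(json_path.read_text())
    df = pd.read_csv(base.with_suffix(".csv"), header=None)
    values = df.to_numpy(dtype=float)
    return STMap(values, kind=meta["kind"], units=meta["units"],
                 frame_interval_s=meta["frame_interval_s"],
                 stride=meta["stride"], column_spacing=meta["column_spacing"],
                 origin=meta.get("origin", ""))


def read_loi(path: str | os.PathLike) -> LineOfInterest:
    """Load LOI control points from a CSV (row,col columns) or JSON list."""
    p = Path(path)
    if p.suffix.lower() == ".json":
        pts = json.loads(p.read_text())
    else:
        pts = pd.read_csv(p, header=None).to_numpy(dtype=float)
    return LineOfInterest(pts)


def write_provenance(out_dir: str | os.PathLike, config: dict) -> Path:
    """Record a machine-readable provenance sidecar for a CLI run."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record = {"software": "stmotility", "version": __version__,
              "config": config}
    p = out / "provenance.json"
    p.write_text(json.dumps(record, indent=2, default=str))
    return p
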