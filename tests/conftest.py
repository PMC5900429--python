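"""Shared fixtures: small synthetic scenes generated at test time."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import stmotility as sm
from stmotility.simulator import _poisson_disc, _render_markers


@pytest.fixture(scope="session")
def peristalsis_run():
    """A short propagating-peristalsis simulation with ground truth."""
    scene = sm.TubeScene(length_px=256, n_frames=60, seed=11, noise_sd=2.0)
    program = sm.ContractionProgram(pattern="peristalsis", amplitude=0.5,
                                    wave_speed=30.0, temporal_frequency=0.25,
                                    spatial_extent=20.0)
    stack, gt = sm.simulate_tube(scene, program)
    return scene, program, stack, gt


@pytest.fixture(scope="session")
def speckle_image():
    """A band-limited speckle texture on the 0-255 scale."""
    rng = np.random.default_rng(42)
    img = ndimage.gaussian_filter(rng.random((96, 128)), 1.5)
    return (img - img.min()) / np.ptp(img) * 255.0


@pytest.fixture(scope="session")
def marker_texture():
    """A dense Gaussian-blob marker texture (frame-like, 0-255 scale)."""
    rng = np.random.default_rng(3)
    H, W = 100, 220
    pts = _poisson_disc(rng, 330, np.array([5.0, 5.0]),
                        np.array([H - 5.0, W - 5.0]), 3.2)
    frame = np.full((H, W), 200.0)
    _render_markers(frame, pts[:, 0], pts[:, 1], 2.0, 110.0)
    return frame


def fourier_shift(img: np.ndarray, d_row: float, d_col: float) -> np.ndarray:
    """Exact sub-pixel translation of a periodic image via the Fourier shift
    theorem (content moves by (+d_row, +d_col))."""
    f = np.fft.fft2(img)
    ky = np.fft.fftfreq(img.shape[0])[:, None]
    kx = np.fft.fftfreq(img.shape[1])[None, :]
    return np.real(np.fft.ifft2(f * np.exp(-2j * np.pi * (ky * d_row + kx * d_col))))
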