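"""Gradient fields and per-cell orientation histograms.

The descriptor pipeline starts from per-pixel gradient magnitude rho and
unsigned orientation gamma in [0, pi).  Each pixel's magnitude is voted into
an m-bin orientation histogram over its 8x8-pixel cell; to suppress aliasing
the vote is split between the two bins whose centers straddle gamma
(circular bilinear interpolation, period pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DimensionError, ParameterError
from .roi import EyePatch

DEFAULT_CELL_SIZE = 8
DEFAULT_BINS = 8


@dataclass(frozen=True)
class GradientField:
    """Per-pixel gradient magnitude (rho >= 0) and orientation (gamma in [0, pi))."""

    rho: np.ndarray
    gamma: np.ndarray


@dataclass(frozen=True)
class CellGrid:
    """Cy x Cx x m array of orientation-vote masses over cell_size cells."""

    hist: np.ndarray
    cell_size: int
    m: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.hist.shape[0], self.hist.shape[1]


def _as_array(patch) -> np.ndarray:
    if isinstance(patch, EyePatch):
        return patch.pixels
    return np.asarray(patch, dtype=np.float64)


def compute_gradients(patch, method: str = "central", sigma: float = 1.0) -> GradientField:
    """Gradient magnitude and unsigned orientation of an image patch.

    ``method="central"`` applies the centered difference mask [-1, 0, 1]
    along x (and its transpose along y); ``method="gaussian"`` convolves with
    first-order Gaussian-derivative kernels at scale ``sigma``.  Borders
    reflect.  Orientation is folded into [0, pi); where rho == 0 it is 0 by
    convention (zero vote mass either way).
    """
    img = _as_array(patch)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise DimensionError(f"patch must be at least 3x3, got shape {img.shape}")
    if method == "central":
        lx = ndimage.correlate1d(img, [-1.0, 0.0, 1.0], axis=1, mode="reflect")
        ly = ndimage.correlate1d(img, [-1.0, 0.0, 1.0], axis=0, mode="reflect")
    elif method == "gaussian":
        if sigma <= 0:
            raise ParameterError(f"sigma must be > 0, got {sigma}")
        lx = ndimage.gaussian_filter(img, sigma, order=(0, 1), mode="reflect")
        ly = ndimage.gaussian_filter(img, sigma, order=(1, 0), mode="reflect")
    else:
        raise ParameterError(f"unknown gradient method {method!r}")
    rho = np.hypot(lx, ly)
    gamma = np.mod(np.arctan2(ly, lx), np.pi)
    gamma[gamma >= np.pi] = 0.0  # fold the rounding edge
    gamma[rho == 0] = 0.0
    return GradientField(rho=rho, gamma=gamma)


def _split_votes(gamma: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized circular bilinear split: lower bin index, upper-bin weight.

    Bin k has width pi/m and center (k + 0.5) * pi/m; the vote interpolates
    between the two nearest centers with wrap-around modulo m.
    """
    t = gamma / (np.pi / m) - 0.5
    fl = np.floor(t)
    frac = t - fl
    b0 = fl.astype(np.int64) % m
    b1 = (b0 + 1) % m
    return b0, b1, frac


def vote_weights(gamma: float, m: int = DEFAULT_BINS) -> tuple[tuple[int, float], tuple[int, float]]:
    """The two orientation bins receiving a pixel's vote and their weights.

    Returns ``((b0, w0), (b1, w1))`` with w0 + w1 == 1.  A gamma at a bin
    center gives that bin the full weight; a gamma on a bin edge splits
    evenly between the adjacent bins (wrapping 0 <-> m-1).
    """
    if m < 2:
        raise ParameterError(f"need at least 2 bins, got {m}")
    if not (0.0 <= gamma < np.pi):
        raise ParameterError(f"gamma must lie in [0, pi), got {gamma}")
    b0, b1, frac = _split_votes(np.asarray(gamma, dtype=np.float64), m)
    return (int(b0), 1.0 - float(frac)), (int(b1), float(frac))


def cell_histograms(grad: GradientField, cell_size: int = DEFAULT_CELL_SIZE, m: int = DEFAULT_BINS) -> CellGrid:
    """Accumulate magnitude-weighted orientation votes into per-cell histograms.

    Each pixel contributes rho split across its two vote bins, so total
    histogram mass equals the total gradient magnitude exactly.
    """
    h, w = grad.rho.shape
    if h % cell_size or w % cell_size:
        raise DimensionError(f"field {h}x{w} not divisible by cell size {cell_size}")
    cy, cx = h // cell_size, w // cell_size
    b0, b1, frac = _split_votes(grad.gamma, m)
    rows = np.arange(h)[:, None] // cell_size
    cols = np.arange(w)[None, :] // cell_size
    cell_index = (rows * cx + cols) * m
    flat0 = (cell_index + b0).ravel()
    flat1 = (cell_index + b1).ravel()
    n = cy * cx * m
    hist = np.bincount(flat0, weights=(grad.rho * (1.0 - frac)).ravel(), minlength=n)
    hist += np.bincount(flat1, weights=(grad.rho * frac).ravel(), minlength=n)
    return CellGrid(hist=hist.reshape(cy, cx, m), cell_size=cell_size, m=m)
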