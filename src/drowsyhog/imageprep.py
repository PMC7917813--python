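"""Frame preprocessing: luma conversion, Gaussian denoising, adaptive
contrast-limited histogram equalization (CLAHE) and downscaling.

Color frames are 8-bit ``H x W x 3`` arrays; grayscale working images are
float ``H x W`` arrays with values in [0, 1].  Light compensation runs on the
color frame (each channel equalized independently); all later stages operate
on the normalized luminance.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import DimensionError, ParameterError

# BT.601 luma weights; night/IR footage is effectively single-channel, for
# which any convex weighting is the identity.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def _require_color(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise DimensionError(f"expected H x W x 3 color image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise DimensionError("empty image")
    return img


def _require_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise DimensionError(f"expected non-empty H x W grayscale image, got shape {img.shape}")
    return img


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit color frame to luminance in [0, 1] (BT.601 weights)."""
    img = _require_color(img).astype(np.float64)
    r, g, b = LUMA_WEIGHTS
    return (r * img[..., 0] + g * img[..., 1] + b * img[..., 2]) / 255.0


def gaussian_kernel(kernel_size: int = 3, sigma: float = 0.5) -> np.ndarray:
    """Normalized 2D Gaussian kernel sampled on a ``kernel_size`` square grid."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ParameterError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    half = kernel_size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_smooth(img: np.ndarray, kernel_size: int = 3, sigma: float = 0.5) -> np.ndarray:
    """Denoise a grayscale image by convolution with a normalized Gaussian.

    Borders are reflected, so constant images are fixed points and total
    intensity is conserved.
    """
    img = _require_gray(img)
    k = gaussian_kernel(kernel_size, sigma)
    return ndimage.convolve(img, k, mode="reflect")


def _clahe_luts(channel: np.ndarray, clip_limit: float, tiles: tuple[int, int]) -> tuple[np.ndarray, int, int]:
    """Per-tile 256-entry LUTs from clipped histograms.

    Clip limit follows the usual "multiples of the uniform bin height"
    convention; clipped excess is redistributed uniformly.  The LUT uses a
    midpoint cumulative mapping, (cdf(v) - hist(v)/2) / N, so a constant
    channel maps onto itself to within one gray level.
    """
    ty, tx = tiles
    h, w = channel.shape
    th = -(-h // ty)  # ceil
    tw = -(-w // tx)
    pad_y, pad_x = th * ty - h, tw * tx - w
    padded = np.pad(channel, ((0, pad_y), (0, pad_x)), mode="reflect")
    npix = th * tw
    limit = max(clip_limit * npix / 256.0, 1.0)

    luts = np.empty((ty, tx, 256), dtype=np.float64)
    for i in range(ty):
        for j in range(tx):
            tile = padded[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
            excess = np.maximum(hist - limit, 0.0).sum()
            hist = np.minimum(hist, limit) + excess / 256.0
            cdf = np.cumsum(hist)
            luts[i, j] = (cdf - 0.5 * hist) / npix * 255.0
    return luts, th, tw


def _clahe_channel(channel: np.ndarray, clip_limit: float, tiles: tuple[int, int]) -> np.ndarray:
    luts, th, tw = _clahe_luts(channel, clip_limit, tiles)
    ty, tx = luts.shape[:2]
    h, w = channel.shape

    # Bilinear interpolation between the four surrounding tile mappings.
    yy = np.clip((np.arange(h) + 0.5) / th - 0.5, 0.0, ty - 1.0)
    xx = np.clip((np.arange(w) + 0.5) / tw - 0.5, 0.0, tx - 1.0)
    y0 = np.minimum(yy.astype(int), ty - 1)
    x0 = np.minimum(xx.astype(int), tx - 1)
    y1 = np.minimum(y0 + 1, ty - 1)
    x1 = np.minimum(x0 + 1, tx - 1)
    fy = (yy - y0)[:, None]
    fx = (xx - x0)[None, :]

    v = channel
    rows0, rows1 = y0[:, None], y1[:, None]
    cols0, cols1 = x0[None, :], x1[None, :]
    out = (
        (1 - fy) * (1 - fx) * luts[rows0, cols0, v]
        + (1 - fy) * fx * luts[rows0, cols1, v]
        + fy * (1 - fx) * luts[rows1, cols0, v]
        + fy * fx * luts[rows1, cols1, v]
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def clahe_equalize(img: np.ndarray, clip_limit: float = 2.0, tiles: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, each channel independently.

    Parameters
    ----------
    img : uint8 color image, H x W x 3.
    clip_limit : histogram clip threshold as a multiple of the uniform bin
        height (larger = more contrast amplification).
    tiles : (rows, cols) of the tile grid over which local histograms are taken.
    """
    img = _require_color(img)
    if clip_limit <= 0:
        raise ParameterError(f"clip_limit must be > 0, got {clip_limit}")
    ty, tx = int(tiles[0]), int(tiles[1])
    if ty < 1 or tx < 1:
        raise ParameterError(f"tiles must be >= (1, 1), got {tiles}")
    img8 = img.astype(np.uint8)
    out = np.empty_like(img8)
    for c in range(3):
        out[..., c] = _clahe_channel(img8[..., c], clip_limit, (ty, tx))
    return out


def resample_matrix(n_in: int, n_out: int, mode: str) -> np.ndarray:
    """1D resampling weight matrix (n_out x n_in).

    ``mode="area"`` integrates exact box overlaps (block means for integer
    shrink factors); ``mode="linear"`` interpolates between pixel centers.
    """
    if n_in < 1 or n_out < 1:
        raise ParameterError("resampling requires positive sizes")
    if n_in == n_out:
        return np.eye(n_in)
    w = np.zeros((n_out, n_in))
    if mode == "area":
        scale = n_in / n_out
        for i in range(n_out):
            lo, hi = i * scale, (i + 1) * scale
            j0, j1 = int(np.floor(lo)), min(int(np.ceil(hi)), n_in)
            for j in range(j0, j1):
                w[i, j] = min(hi, j + 1) - max(lo, j)
            w[i] /= scale
    elif mode == "linear":
        for i in range(n_out):
            c = np.clip((i + 0.5) * n_in / n_out - 0.5, 0, n_in - 1)
            j0 = int(np.floor(c))
            j1 = min(j0 + 1, n_in - 1)
            f = c - j0
            w[i, j0] += 1 - f
            w[i, j1] += f
    else:  # pragma: no cover - internal misuse
        raise ParameterError(f"unknown resampling mode {mode!r}")
    return w


def resample(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Resize a 2D float image: area averaging when shrinking an axis,
    bilinear when growing it."""
    img = _require_gray(img)
    oh, ow = out_hw
    wy = resample_matrix(img.shape[0], oh, "area" if oh <= img.shape[0] else "linear")
    wx = resample_matrix(img.shape[1], ow, "area" if ow <= img.shape[1] else "linear")
    return wy @ img @ wx.T


def downscale(img: np.ndarray, factor: float):
    """Reduce resolution by ``factor`` in (0, 1] using area averaging.

    Accepts either a float grayscale image or an 8-bit color frame and
    returns the same kind.  ``factor=1`` is the identity.
    """
    if not (0.0 < factor <= 1.0):
        raise ParameterError(f"downscale factor must be in (0, 1], got {factor}")
    img = np.asarray(img)
    if factor == 1.0:
        return img.copy()
    oh = max(1, int(round(img.shape[0] * factor)))
    ow = max(1, int(round(img.shape[1] * factor)))
    if img.ndim == 2:
        wy = resample_matrix(img.shape[0], oh, "area")
        wx = resample_matrix(img.shape[1], ow, "area")
        return wy @ img.astype(np.float64) @ wx.T
    img = _require_color(img)
    wy = resample_matrix(img.shape[0], oh, "area")
    wx = resample_matrix(img.shape[1], ow, "area")
    out = np.empty((oh, ow, 3))
    for c in range(3):
        out[..., c] = wy @ img[..., c].astype(np.float64) @ wx.T
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
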