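"""Binarized orientation-shifted HOG (BOSH) descriptor and the real-valued
HOG baseline.

A BOSH descriptor compares the m-bin orientation histograms of two cells
under every cyclic bin shift eps in 0..m-1:

    b(k, eps) = 1  iff  v1(k) >= v2((k + eps) mod m)

yielding m*m bits per cell pair.  Pairs are taken within each overlapping
2x2-cell block (6 unordered pairs in canonical raster order: TL-TR, TL-BL,
TL-BR, TR-BL, TR-BR, BL-BR), blocks enumerated raster-order with a 1-cell
stride.  Because the comparison only uses order relations between histogram
masses, the bits are invariant to any common positive rescaling of the image
— no block normalization is needed.  Bit order (block-major, then pair, then
shift-major, then bin) is part of the serialized format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DimensionError, ParameterError
from .hog import DEFAULT_BINS, DEFAULT_CELL_SIZE, CellGrid

MAGIC = b"BOSHDESC"
FORMAT_VERSION = 1

#: cell indices within a 2x2 block ordered TL, TR, BL, BR
BLOCK_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class DescriptorLayout:
    """Everything that fixes bit/value positions in a descriptor."""

    patch_w: int
    patch_h: int
    cell_size: int = DEFAULT_CELL_SIZE
    m: int = DEFAULT_BINS
    scheme: str = "bosh"  # "bosh" | "hog"
    pair_scope: str = "block"  # "block" | "grid-adjacent"

    def as_dict(self) -> dict:
        return {
            "patch_w": self.patch_w,
            "patch_h": self.patch_h,
            "cell_size": self.cell_size,
            "m": self.m,
            "scheme": self.scheme,
            "pair_scope": self.pair_scope,
        }


@dataclass(frozen=True)
class BoshVector:
    bits: np.ndarray  # 1D uint8 array of 0/1
    layout: DescriptorLayout


@dataclass(frozen=True)
class HogVector:
    values: np.ndarray  # 1D non-negative floats, per-block L2-normalized
    layout: DescriptorLayout


def _grid_geometry(patch_dims: tuple[int, int], cell_size: int) -> tuple[int, int]:
    w, h = patch_dims
    if w % cell_size or h % cell_size:
        raise DimensionError(f"patch {w}x{h} not divisible by cell size {cell_size}")
    return h // cell_size, w // cell_size


def descriptor_length(
    patch_dims: tuple[int, int],
    cell_size: int = DEFAULT_CELL_SIZE,
    m: int = DEFAULT_BINS,
    scheme: str = "bosh",
    pair_scope: str = "block",
) -> int:
    """Closed-form descriptor length for ``(width, height)`` patches."""
    cy, cx = _grid_geometry(patch_dims, cell_size)
    if cy < 2 or cx < 2:
        raise DimensionError(f"need at least a 2x2 cell grid, got {cy}x{cx}")
    n_blocks = (cy - 1) * (cx - 1)
    if scheme == "hog":
        return n_blocks * 4 * m
    if scheme != "bosh":
        raise ParameterError(f"unknown scheme {scheme!r}")
    if pair_scope == "block":
        return n_blocks * len(BLOCK_PAIRS) * m * m
    if pair_scope == "grid-adjacent":
        n_pairs = cy * (cx - 1) + (cy - 1) * cx
        return n_pairs * m * m
    raise ParameterError(f"unknown pair_scope {pair_scope!r}")


def _shift_index(m: int) -> np.ndarray:
    """(m, m) index table: row eps, column k -> (k + eps) mod m."""
    k = np.arange(m)
    return (k[None, :] + k[:, None]) % m


def binarize_pair(v1: np.ndarray, v2: np.ndarray, m: int = DEFAULT_BINS) -> np.ndarray:
    """All m*m shifted-order bits between two m-bin histograms.

    Output is flat, shift-major: bit index ``eps * m + k`` holds
    ``v1[k] >= v2[(k + eps) % m]``.  Ties yield 1.
    """
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if v1.shape != (m,) or v2.shape != (m,):
        raise ParameterError(f"histograms must both have length {m}, got {v1.shape} and {v2.shape}")
    bits = v1[None, :] >= v2[_shift_index(m)]
    return bits.astype(np.uint8).ravel()


def _block_cells(hist: np.ndarray) -> tuple[np.ndarray, ...]:
    """The four cell histograms of every 2x2 block, raster order TL, TR, BL, BR."""
    return hist[:-1, :-1], hist[:-1, 1:], hist[1:, :-1], hist[1:, 1:]


def extract_bosh(grid: CellGrid, pair_scope: str = "block") -> BoshVector:
    """BOSH bit vector of a cell grid."""
    cy, cx = grid.shape
    if cy < 2 or cx < 2:
        raise DimensionError(f"need at least a 2x2 cell grid, got {cy}x{cx}")
    m = grid.m
    idx = _shift_index(m)
    if pair_scope == "block":
        cells = _block_cells(grid.hist)
        # (By, Bx, 6 pairs, m shifts, m bins), flattened C-order gives the
        # documented block-major / pair-major / shift-major / bin order.
        pair_bits = [
            cells[a][:, :, None, :] >= cells[b][:, :, idx] for a, b in BLOCK_PAIRS
        ]
        bits = np.stack(pair_bits, axis=2)
    elif pair_scope == "grid-adjacent":
        horiz = grid.hist[:, :-1][:, :, None, :] >= grid.hist[:, 1:][:, :, idx]
        vert = grid.hist[:-1][:, :, None, :] >= grid.hist[1:][:, :, idx]
        bits = np.concatenate([horiz.reshape(-1, m, m), vert.reshape(-1, m, m)])
    else:
        raise ParameterError(f"unknown pair_scope {pair_scope!r}")
    layout = DescriptorLayout(
        patch_w=cx * grid.cell_size, patch_h=cy * grid.cell_size,
        cell_size=grid.cell_size, m=m, scheme="bosh", pair_scope=pair_scope,
    )
    return BoshVector(bits=bits.astype(np.uint8).ravel(), layout=layout)


def extract_hog_baseline(grid: CellGrid, eps_norm: float = 1e-6) -> HogVector:
    """Standard block-normalized HOG vector (the comparison baseline).

    Per 2x2 block the four cell histograms are concatenated and
    L2-normalized with guard ``eps_norm``; blocks concatenate raster-order.
    """
    cy, cx = grid.shape
    if cy < 2 or cx < 2:
        raise DimensionError(f"need at least a 2x2 cell grid, got {cy}x{cx}")
    m = grid.m
    tl, tr, bl, br = _block_cells(grid.hist)
    blocks = np.concatenate([tl, tr, bl, br], axis=2).reshape(-1, 4 * m)
    norms = np.sqrt((blocks**2).sum(axis=1, keepdims=True) + eps_norm**2)
    values = blocks / norms
    layout = DescriptorLayout(
        patch_w=cx * grid.cell_size, patch_h=cy * grid.cell_size,
        cell_size=grid.cell_size, m=m, scheme="hog",
    )
    return HogVector(values=values.ravel(), layout=layout)


# ---------------------------------------------------------------------------
# descriptor containers

def save_descriptors(path: str | Path, bit_rows: np.ndarray, layout: DescriptorLayout) -> None:
    """Write a packed binary descriptor container.

    Format: 8-byte magic, one JSON header line (version, layout, n_samples,
    n_bits), then each sample's bits packed 8 per byte, first bit in the
    most significant position, rows padded to a byte boundary.
    """
    rows = np.atleast_2d(np.asarray(bit_rows, dtype=np.uint8))
    header = {
        "version": FORMAT_VERSION,
        "layout": layout.as_dict(),
        "n_samples": int(rows.shape[0]),
        "n_bits": int(rows.shape[1]),
    }
    packed = np.packbits(rows, axis=1)
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write((json.dumps(header, sort_keys=True) + "\n").encode())
        fh.write(packed.tobytes())


def load_descriptors(path: str | Path) -> tuple[np.ndarray, DescriptorLayout]:
    with open(path, "rb") as fh:
        if fh.read(len(MAGIC)) != MAGIC:
            raise ParameterError(f"{path}: not a descriptor container")
        header = json.loads(fh.readline().decode())
        if header["version"] != FORMAT_VERSION:
            raise ParameterError(f"{path}: unsupported version {header['version']}")
        n, nbits = header["n_samples"], header["n_bits"]
        packed = np.frombuffer(fh.read(), dtype=np.uint8).reshape(n, -1)
    rows = np.unpackbits(packed, axis=1)[:, :nbits]
    return rows, DescriptorLayout(**header["layout"])


def save_descriptors_text(path: str | Path, bit_rows: np.ndarray) -> None:
    """Plain-text export: one row of 0/1 characters per sample."""
    rows = np.atleast_2d(np.asarray(bit_rows, dtype=np.uint8))
    with open(path, "w", encoding="utf-8") as fh:
        for row in rows:
            fh.write("".join("1" if b else "0" for b in row) + "\n")


def load_descriptors_text(path: str | Path) -> np.ndarray:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append([1 if c == "1" else 0 for c in line])
    return np.asarray(rows, dtype=np.uint8)
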