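"""2D discrete cosine transform, block partitioning and block statistics.

The transform is the orthonormal type-II DCT of an M x N matrix A,

    B[p, q] = a_p a_q * sum_{m,n} A[m, n]
              * cos(pi (2m+1) p / 2M) * cos(pi (2n+1) q / 2N),

with a_0 = 1/sqrt(M) and a_p = sqrt(2/M) for p >= 1 (likewise in q).
This scaling is orthonormal, so the transform conserves Frobenius
energy (Parseval) and is exactly invertible.  B[0, 0] is the DC term
(scaled image mean); "DC removal" zeroes it so only alternating
spatial content remains.

For segmentation the sonogram is tiled into non-overlapping square
blocks (minimum 4 x 4; 32 x 32 and 16 x 16 are the useful sizes for
1024 x 384 sonograms) and each block is summarised by the mean
absolute DCT coefficient excluding DC — a scalar spatial-frequency
activity measure that is invariant to the block's mean brightness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.fft import dctn, idctn

from .rf_io import BModeImage

__all__ = [
    "SpectrumMatrix",
    "BlockGrid",
    "dct2",
    "idct2",
    "remove_dc",
    "partition_blocks",
    "reassemble",
    "block_mean_frequency",
    "MIN_BLOCK_SIZE",
    "DEFAULT_BLOCK_SIZE",
]

MIN_BLOCK_SIZE = 4
DEFAULT_BLOCK_SIZE = 32


@dataclass(frozen=True)
class SpectrumMatrix:
    """DCT coefficient matrix of an image or block."""

    coeffs: np.ndarray
    dc_removed: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs, dtype=np.float64)
        if c.ndim != 2:
            raise ValueError("coefficient matrix must be 2D")
        if self.dc_removed and c[0, 0] != 0.0:
            raise ValueError("dc_removed is set but coeffs[0,0] != 0")
        object.__setattr__(self, "coeffs", c)

    @property
    def shape(self) -> tuple[int, int]:
        return self.coeffs.shape


@dataclass(frozen=True)
class BlockGrid:
    """Non-overlapping square tiling of an image.

    ``blocks`` has shape (grid_rows, grid_cols, block_size, block_size).
    Trailing rows/columns that do not fill a whole block are cropped;
    ``crop_origin`` records the top-left corner of the retained region
    (always (0, 0) here — cropping discards the trailing remainder).
    """

    blocks: np.ndarray
    block_size: int
    crop_origin: tuple[int, int] = (0, 0)

    @property
    def grid_rows(self) -> int:
        return self.blocks.shape[0]

    @property
    def grid_cols(self) -> int:
        return self.blocks.shape[1]

    @property
    def n_blocks(self) -> int:
        return self.grid_rows * self.grid_cols


def _as_matrix(a: Union[np.ndarray, BModeImage]) -> np.ndarray:
    if isinstance(a, BModeImage):
        a = a.pixels
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("input must be a nonempty 2D matrix")
    if not np.all(np.isfinite(a)):
        raise ValueError("input contains non-finite values")
    return a


def dct2(a: Union[np.ndarray, BModeImage]) -> SpectrumMatrix:
    """Orthonormal 2D type-II DCT.

    Raises ``ValueError`` on empty or non-finite input.
    """
    a = _as_matrix(a)
    return SpectrumMatrix(coeffs=dctn(a, type=2, norm="ortho"))


def idct2(s: SpectrumMatrix) -> np.ndarray:
    """Inverse of :func:`dct2` (orthonormal type-III DCT)."""
    return idctn(s.coeffs, type=2, norm="ortho")


def remove_dc(s: SpectrumMatrix) -> SpectrumMatrix:
    """Zero the (0, 0) coefficient; idempotent, all others untouched."""
    c = s.coeffs.copy()
    c[0, 0] = 0.0
    return SpectrumMatrix(coeffs=c, dc_removed=True)


def partition_blocks(
    b: Union[np.ndarray, BModeImage], block_size: int = DEFAULT_BLOCK_SIZE
) -> BlockGrid:
    """Tile the image into non-overlapping ``block_size`` squares.

    The grid is floor(height/block_size) x floor(width/block_size);
    a trailing remainder in either dimension is cropped away.
    """
    if block_size < MIN_BLOCK_SIZE:
        raise ValueError(
            f"block_size must be >= {MIN_BLOCK_SIZE}, got {block_size}"
        )
    a = _as_matrix(b)
    h, w = a.shape
    gr, gc = h // block_size, w // block_size
    if gr < 1 or gc < 1:
        raise ValueError(
            f"image {h}x{w} smaller than one {block_size}x{block_size} block"
        )
    cropped = a[: gr * block_size, : gc * block_size]
    blocks = (
        cropped.reshape(gr, block_size, gc, block_size)
        .transpose(0, 2, 1, 3)
        .copy()
    )
    return BlockGrid(blocks=blocks, block_size=block_size)


def reassemble(grid: BlockGrid) -> np.ndarray:
    """Stitch a BlockGrid back into the cropped image (inverse of tiling)."""
    gr, gc, s, _ = grid.blocks.shape
    return grid.blocks.transpose(0, 2, 1, 3).reshape(gr * s, gc * s)


def block_mean_frequency(tile: np.ndarray) -> float:
    """Mean absolute DCT coefficient of a square tile, DC excluded.

    This is the per-block spatial-frequency activity statistic used for
    segmentation: zero for a constant tile, invariant to adding a
    constant, and large for high-frequency texture such as speckle.
    """
    tile = _as_matrix(tile)
    s0, s1 = tile.shape
    if s0 != s1:
        raise ValueError(f"tile must be square, got {s0}x{s1}")
    if s0 < MIN_BLOCK_SIZE:
        raise ValueError(f"tile side must be >= {MIN_BLOCK_SIZE}, got {s0}")
    c = np.abs(dctn(tile, type=2, norm="ortho"))
    return float((c.sum() - c[0, 0]) / (c.size - 1))


def block_statistics(grid: BlockGrid) -> np.ndarray:
    """Vectorised :func:`block_mean_frequency` over every tile.

    Returns a (grid_rows, grid_cols) float matrix.
    """
    c = np.abs(dctn(grid.blocks, type=2, norm="ortho", axes=(-2, -1)))
    n = grid.block_size * grid.block_size
    return (c.sum(axis=(-2, -1)) - c[..., 0, 0]) / (n - 1)
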