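"""Spatial sharpness map S2, fusion with S1 into S3, and pooling to S.

The spatial cue is local contrast: the total variation of a 2x2 pixel
neighborhood, v = (1/255) * sum of absolute differences over its six
unordered pixel pairs.  Per analysis block, S2 is the maximum such v over
all 2x2 sub-blocks, divided by 4 to keep the score near [0, 1].  The
spectral and spatial maps are fused geometrically,

    S3 = S1^mu * S2^(1-mu),    mu = 0.5,

and the scalar score S is the mean of the top 1% of S3 block values, which
suppresses the influence of flat or noisy regions.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .spectral import BlockGrid, spectral_map

DEFAULT_MU = 0.5
DEFAULT_POOL_FRACTION = 0.01


@dataclasses.dataclass
class SharpnessScore:
    """Spectral (S1), spatial (S2) and fused (S3) maps plus the pooled S."""

    s1_map: BlockGrid
    s2_map: BlockGrid
    s3_map: BlockGrid
    S: float
    mu: float = DEFAULT_MU
    pool_fraction: float = DEFAULT_POOL_FRACTION

    def __post_init__(self) -> None:
        if not (self.s1_map.same_geometry(self.s2_map)
                and self.s1_map.same_geometry(self.s3_map)):
            raise ValueError("S1/S2/S3 maps must share one block geometry")
        if not 0.0 <= self.S <= 1.0:
            raise ValueError("pooled S must lie in [0, 1]")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if not 0.0 < self.pool_fraction <= 1.0:
            raise ValueError("pool_fraction must lie in (0, 1]")


def total_variation(block: np.ndarray) -> float:
    """8-neighbor total variation of a block on the [0, 255] scale.

    Sum over every pixel of the absolute differences to its eight
    neighbors (replicate padding at the border), divided by 255.
    """
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2 or min(block.shape) < 3:
        raise ValueError("total_variation requires a block of at least 3x3")
    padded = np.pad(block, 1, mode="edge")
    total = 0.0
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            shifted = padded[1 + di:padded.shape[0] - 1 + di,
                             1 + dj:padded.shape[1] - 1 + dj]
            total += float(np.abs(block - shifted).sum())
    return total / 255.0


def _pairwise_2x2_tv(block: np.ndarray) -> np.ndarray:
    """v for every 2x2 sub-block (stride 1): sum of |diff| over the 6 pairs."""
    a = block[:-1, :-1]
    b = block[:-1, 1:]
    c = block[1:, :-1]
    d = block[1:, 1:]
    v = (np.abs(a - b) + np.abs(a - c) + np.abs(a - d)
         + np.abs(b - c) + np.abs(b - d) + np.abs(c - d))
    return v / 255.0


def spatial_block_score(block: np.ndarray) -> float:
    """S2 of one block: max 2x2-neighborhood total variation, divided by 4."""
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2 or min(block.shape) < 2:
        raise ValueError("spatial_block_score requires a block of at least 2x2")
    return float(_pairwise_2x2_tv(block).max()) / 4.0


def spatial_map(img: np.ndarray, grid: BlockGrid | None = None) -> BlockGrid:
    """Per-block spatial sharpness map S2."""
    img = np.asarray(img, dtype=np.float64)
    if grid is None:
        grid = BlockGrid.cover(img.shape)
    # one vectorized pass over the whole image, then a max per block window
    v = _pairwise_2x2_tv(img)
    values = np.zeros_like(grid.values)
    b = grid.block_size
    for i, r in enumerate(grid.origin_rows):
        for j, c in enumerate(grid.origin_cols):
            values[i, j] = v[r:r + b - 1, c:c + b - 1].max() / 4.0
    return grid.with_values(values)


def _pow0(base: np.ndarray, exponent: float) -> np.ndarray:
    """base**exponent with the 0**0 = 0 convention."""
    base = np.asarray(base, dtype=np.float64)
    return np.where(base == 0.0, 0.0, np.power(base, exponent,
                                               where=base > 0,
                                               out=np.zeros_like(base)))


def fuse_maps(s1_map: BlockGrid, s2_map: BlockGrid,
              mu: float = DEFAULT_MU) -> BlockGrid:
    """Geometric fusion S3 = S1^mu * S2^(1-mu) on a shared block grid."""
    if not s1_map.same_geometry(s2_map):
        raise ValueError("S1 and S2 maps must share one block geometry")
    if np.any(s1_map.values < 0) or np.any(s2_map.values < 0):
        raise ValueError("sharpness maps must be non-negative")
    fused = _pow0(s1_map.values, mu) * _pow0(s2_map.values, 1.0 - mu)
    return s1_map.with_values(fused)


def pool_top_fraction(grid: BlockGrid,
                      fraction: float = DEFAULT_POOL_FRACTION) -> float:
    """Mean of the largest ``ceil(fraction * n_blocks)`` block values."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    flat = grid.values.ravel()
    if flat.size == 0:
        raise ValueError("cannot pool an empty block grid")
    n_top = max(1, int(np.ceil(fraction * flat.size)))
    top = np.partition(flat, flat.size - n_top)[flat.size - n_top:]
    return float(top.mean())


def spectral_spatial_score(img: np.ndarray,
                           block_size: int = 32, step: int = 16,
                           mu: float = DEFAULT_MU,
                           pool_fraction: float = DEFAULT_POOL_FRACTION,
                           tau1: float = -3.0,
                           tau2: float = 2.0) -> SharpnessScore:
    """Full spectral-spatial score of one image (normally a cartoon component).

    Builds the shared block grid, computes the S1 and S2 maps, fuses them
    and pools the top fraction into the scalar S.
    """
    img = np.asarray(img, dtype=np.float64)
    grid = BlockGrid.cover(img.shape, block_size, step)
    s1 = spectral_map(img, grid, tau1=tau1, tau2=tau2)
    s2 = spatial_map(img, grid)
    s3 = fuse_maps(s1, s2, mu)
    pooled = pool_top_fraction(s3, pool_fraction)
    return SharpnessScore(s1_map=s1, s2_map=s2, s3_map=s3,
                          S=min(pooled, 1.0), mu=mu,
                          pool_fraction=pool_fraction)
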