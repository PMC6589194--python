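"""Block-wise spectral sharpness from the log-log amplitude-spectrum slope.

Natural-image amplitude spectra follow an approximate power law ("1/f law"):
on log-log axes the radially collapsed magnitude spectrum is close to a
straight line.  Blur steepens the decay, so the absolute slope alpha of the
fitted line is a blur indicator.  Per 32x32 block the slope is mapped through
a sigmoid to the spectral sharpness S1 in (0, 1):

    S1 = 1 - 1 / (1 + exp(tau1 * (alpha - tau2)))

with tau1 = -3 and tau2 = 2, so a block with alpha = 2 scores exactly 0.5 and
steeper (more blurred) blocks score lower.
"""

from __future__ import annotations

import dataclasses

import numpy as np

DEFAULT_BLOCK_SIZE = 32
DEFAULT_STEP = 16
DEFAULT_TAU1 = -3.0
DEFAULT_TAU2 = 2.0

#: Number of orientation samples the radial collapse represents.  The summed
#: magnitude z(f) over orientations is computed as (ring mean) * N_THETA so
#: that the log-log slope is that of the per-sample amplitude decay.
N_THETA = 360


class DegenerateSpectrumError(ValueError):
    """Raised when a block has too little spectral content to fit a slope."""


@dataclasses.dataclass
class BlockGrid:
    """A grid of overlapping square analysis blocks with per-block values."""

    block_size: int
    step: int
    origin_rows: np.ndarray
    origin_cols: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.block_size < 8:
            raise ValueError("block_size must be >= 8")
        if not 1 <= self.step <= self.block_size:
            raise ValueError("step must satisfy 1 <= step <= block_size")
        self.origin_rows = np.asarray(self.origin_rows, dtype=np.intp)
        self.origin_cols = np.asarray(self.origin_cols, dtype=np.intp)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.origin_rows), len(self.origin_cols)):
            raise ValueError("values shape must match block-origin grid")

    @classmethod
    def cover(cls, shape: tuple[int, int], block_size: int = DEFAULT_BLOCK_SIZE,
              step: int = DEFAULT_STEP) -> "BlockGrid":
        """Grid of blocks fully inside an image of the given shape."""
        m, n = shape
        if m < block_size or n < block_size:
            raise ValueError(
                f"image {m}x{n} smaller than one {block_size}x{block_size} block"
            )
        rows = np.arange(0, m - block_size + 1, step)
        cols = np.arange(0, n - block_size + 1, step)
        values = np.zeros((len(rows), len(cols)))
        return cls(block_size, step, rows, cols, values)

    def same_geometry(self, other: "BlockGrid") -> bool:
        return (
            self.block_size == other.block_size
            and self.step == other.step
            and np.array_equal(self.origin_rows, other.origin_rows)
            and np.array_equal(self.origin_cols, other.origin_cols)
        )

    def with_values(self, values: np.ndarray) -> "BlockGrid":
        return BlockGrid(self.block_size, self.step, self.origin_rows,
                         self.origin_cols, values)

    def iter_blocks(self, img: np.ndarray):
        b = self.block_size
        for i, r in enumerate(self.origin_rows):
            for j, c in enumerate(self.origin_cols):
                yield i, j, img[r:r + b, c:c + b]


@dataclasses.dataclass
class RadialSpectrum:
    """Radially collapsed amplitude spectrum: z(f) per normalized frequency."""

    freqs: np.ndarray
    magnitudes: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.magnitudes = np.asarray(self.magnitudes, dtype=np.float64)
        if len(self.freqs) != len(self.magnitudes):
            raise ValueError("freqs and magnitudes must have equal length")
        if np.any(np.diff(self.freqs) <= 0) or np.any(self.freqs <= 0):
            raise ValueError("freqs must be strictly increasing and positive")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")


def radial_spectrum(block: np.ndarray, m: int | None = None) -> RadialSpectrum:
    """Collapse a square block's windowed DFT magnitude onto radial bins.

    The block mean (DC) is removed and a Hanning window applied before the
    DFT.  Each frequency-plane sample gets the normalized radius
    ``f = sqrt((u/(m/2))^2 + (v/(m/2))^2)`` and is assigned to the nearest
    radial bin of width ``2/m``; z(f) is the per-bin mean magnitude scaled
    by a fixed orientation count, i.e. the magnitude summed over a uniform
    set of orientations.  The DC bin is excluded.
    """
    block = np.asarray(block, dtype=np.float64)
    if block.ndim != 2 or block.shape[0] != block.shape[1]:
        raise ValueError("radial_spectrum requires a square block")
    if m is None:
        m = block.shape[0]
    elif m != block.shape[0]:
        raise ValueError(f"block side {block.shape[0]} != m={m}")

    window = np.hanning(m)
    windowed = (block - block.mean()) * np.outer(window, window)
    mag = np.abs(np.fft.fftshift(np.fft.fft2(windowed)))

    idx = np.arange(m) - m // 2
    u, v = np.meshgrid(idx, idx, indexing="ij")
    half = m / 2.0
    radius = np.sqrt((u / half) ** 2 + (v / half) ** 2)
    # nearest bin of width 2/m in normalized-frequency units
    bins = np.rint(radius * half).astype(np.intp)

    counts = np.bincount(bins.ravel())
    sums = np.bincount(bins.ravel(), weights=mag.ravel())
    k = np.arange(len(counts))
    keep = (k > 0) & (counts > 0)
    means = sums[keep] / counts[keep]
    freqs = k[keep] / half
    return RadialSpectrum(freqs=freqs, magnitudes=means * N_THETA)


def spectral_slope(spec: RadialSpectrum) -> float:
    """Absolute log-log slope of z(f): alpha in the power-law fit z ~ f^-alpha.

    Ordinary least squares of log z against log f over all bins with
    positive magnitude; at least three such bins are required.
    """
    mask = spec.magnitudes > 0
    if int(mask.sum()) < 3:
        raise DegenerateSpectrumError(
            f"only {int(mask.sum())} usable radial bins; need >= 3"
        )
    slope, _ = np.polyfit(np.log(spec.freqs[mask]),
                          np.log(spec.magnitudes[mask]), 1)
    return float(-slope)


def sharpness_sigmoid(alpha: float, tau1: float = DEFAULT_TAU1,
                      tau2: float = DEFAULT_TAU2) -> float:
    """Map a spectral slope to S1 in (0, 1); decreasing in alpha for tau1 < 0."""
    return float(1.0 - 1.0 / (1.0 + np.exp(tau1 * (alpha - tau2))))


def spectral_map(img: np.ndarray, grid: BlockGrid | None = None,
                 tau1: float = DEFAULT_TAU1,
                 tau2: float = DEFAULT_TAU2) -> BlockGrid:
    """Per-block spectral sharpness map S1.

    Blocks whose spectrum is too flat to fit (fewer than three populated
    radial bins, e.g. constant blocks) score 0: flat regions carry no
    sharpness evidence.
    """
    img = np.asarray(img, dtype=np.float64)
    if grid is None:
        grid = BlockGrid.cover(img.shape)
    values = np.zeros_like(grid.values)
    for i, j, block in grid.iter_blocks(img):
        try:
            alpha = spectral_slope(radial_spectrum(block))
        except DegenerateSpectrumError:
            values[i, j] = 0.0
        else:
            values[i, j] = sharpness_sigmoid(alpha, tau1, tau2)
    return grid.with_values(values)
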