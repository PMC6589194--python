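"""Reading and writing micrographs and score tables.

Everything downstream operates on one canonical representation: a 2-D float
array of intensities on a nominal [0, 255] scale.  Source images may be 8- or
16-bit PNG/TIFF, single- or multi-channel; multi-channel frames are collapsed
to luminance with the ITU-R BT.601 weights.
"""

from __future__ import annotations

import dataclasses
import os
from typing import TYPE_CHECKING, Iterable, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .fusion import QualityRecord

#: Minimum image side: one 32x32 analysis block plus margin.
MIN_SIDE = 64

#: ITU-R BT.601 luminance weights for R, G, B.
BT601_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclasses.dataclass
class Micrograph:
    """A single-channel micrograph.

    Parameters
    ----------
    pixels
        2-D array of intensities in ``[0, intensity_scale]`` (row-major,
        origin top-left).
    intensity_scale
        Nominal maximum of the source bit depth (255 for 8-bit, 65535 for
        16-bit sources).
    identifier
        Source path or synthetic label.
    """

    pixels: np.ndarray
    intensity_scale: float = 255.0
    identifier: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("Micrograph pixels must be a 2-D array")
        m, n = self.pixels.shape
        if m < MIN_SIDE or n < MIN_SIDE:
            raise ValueError(
                f"image {self.identifier!r} is {m}x{n}; "
                f"minimum supported size is {MIN_SIDE}x{MIN_SIDE}"
            )
        if not np.isfinite(self.pixels).all():
            raise ValueError("Micrograph contains non-finite pixels")
        if self.pixels.min() < 0 or self.pixels.max() > self.intensity_scale:
            raise ValueError(
                "pixel values outside [0, intensity_scale="
                f"{self.intensity_scale}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def to_canonical(self) -> np.ndarray:
        """Pixels rescaled to the canonical [0, 255] floating-point range."""
        return self.pixels * (255.0 / self.intensity_scale)


def as_canonical(img: Union[Micrograph, np.ndarray]) -> np.ndarray:
    """Coerce a :class:`Micrograph` or bare array to canonical float pixels.

    Bare arrays are assumed to already be on the [0, 255] scale; this keeps
    the low-level map operations usable on small test grids that are below
    the Micrograph minimum size.
    """
    if isinstance(img, Micrograph):
        return img.to_canonical()
    return np.asarray(img, dtype=np.float64)


def rgb_to_luminance(frame: np.ndarray) -> np.ndarray:
    """Collapse an (M, N, 3) or (M, N, 4) frame to BT.601 luminance."""
    if frame.ndim != 3 or frame.shape[2] not in (3, 4):
        raise ValueError("expected an (M, N, 3) or (M, N, 4) frame")
    return frame[..., :3].astype(np.float64) @ BT601_WEIGHTS


def _scale_for_dtype(dtype: np.dtype) -> float:
    if dtype == np.uint8:
        return 255.0
    if dtype == np.uint16:
        return 65535.0
    if np.issubdtype(dtype, np.integer):
        return float(np.iinfo(dtype).max)
    # float sources: assume already on the canonical scale
    return 255.0


def load_micrograph(path: Union[str, os.PathLike]) -> Micrograph:
    """Read a PNG or TIFF micrograph into a :class:`Micrograph`.

    Multi-channel frames are converted to BT.601 luminance; the intensity
    scale is recorded from the source bit depth.
    """
    try:
        frame = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc
    scale = _scale_for_dtype(frame.dtype)
    if frame.ndim == 3:
        pixels = rgb_to_luminance(frame)
    elif frame.ndim == 2:
        pixels = frame.astype(np.float64)
    else:
        raise OSError(f"unsupported image dimensionality in {os.fspath(path)!r}")
    return Micrograph(pixels=pixels, intensity_scale=scale,
                      identifier=os.fspath(path))


def write_micrograph(img: Micrograph, path: Union[str, os.PathLike]) -> None:
    """Write a micrograph as 8- or 16-bit PNG/TIFF depending on its scale."""
    dtype = np.uint16 if img.intensity_scale > 255 else np.uint8
    data = np.clip(np.round(img.pixels), 0, img.intensity_scale).astype(dtype)
    iio.imwrite(path, data)


def write_scores(records: Iterable["QualityRecord"],
                 path: Union[str, os.PathLike]) -> None:
    """Write per-image scores as CSV with header ``id,S,d,Q``.

    The ``Q`` column is left empty for records that have not been through
    batch normalization yet.  Row order follows input order; floats carry
    at least 6 significant digits.
    """
    records = list(records)
    if not records:
        raise ValueError("write_scores requires at least one record")
    frame = pd.DataFrame(
        {
            "id": [r.identifier for r in records],
            "S": [f"{r.S:.8g}" for r in records],
            "d": [f"{r.d:.8g}" for r in records],
            "Q": ["" if r.Q is None else f"{r.Q:.8g}" for r in records],
        }
    )
    try:
        frame.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write scores to {os.fspath(path)!r}: {exc}") from exc


def read_scores(path: Union[str, os.PathLike]) -> pd.DataFrame:
    """Read a score CSV written by :func:`write_scores`."""
    return pd.read_csv(path, dtype={"id": str})


def read_mos(path: Union[str, os.PathLike]) -> pd.DataFrame:
    """Read a mean-opinion-score table with schema ``id,mos``."""
    frame = pd.read_csv(path, dtype={"id": str})
    if not {"id", "mos"}.issubset(frame.columns):
        raise ValueError("MOS table must have columns 'id' and 'mos'")
    return frame
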