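"""Maximum-local-variation map and the edge-sparsity blur metric d.

Per pixel, the MLV is the largest absolute intensity difference to any of
its eight neighbors; edges of the MLV map concentrate where the image has
strong transitions.  Edge pixels are detected directionally (Sobel
derivative + non-maximum suppression along the scan direction with a
relative threshold), each detected pixel gets a Marziliano-style width
(distance between the local extrema of the MLV profile bracketing it), and
the per-direction sparsity statistics are combined as

    d = sqrt(d_v^2 + d_h^2).

Two readings of "sparsity" are provided:

``width``
    mean Marziliano edge width over detected edge pixels (grows with blur);
``spacing``
    average distance between edge pixels along scan lines, computed as the
    mean segment length when every scan line is cut at its detected edge
    pixels (the inverse linear density of edge pixels).  Blur produces more
    edge pixels, so this shrinks as blur increases.

The shipped default is ``spacing``: on the graded-blur calibration suite it
is the reading under which d decreases monotonically as blur increases,
matching the reported behavior of the metric.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from scipy import ndimage

DEFAULT_THRESHOLD_FRACTION = 0.1
#: Calibrated on the synthetic graded-blur suite: the mode under which d
#: decreases monotonically with blur.
DEFAULT_SPARSITY_MODE: "SparsityMode" = "spacing"

Direction = Literal["vertical", "horizontal"]
SparsityMode = Literal["width", "spacing"]


@dataclasses.dataclass
class MLVMap:
    """Per-pixel maximum local variation; zero everywhere iff input constant."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("MLV values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclasses.dataclass
class EdgeSparsity:
    """Directional sparsities and their Euclidean combination."""

    d_v: float
    d_h: float
    d: float
    n_edges_v: int
    n_edges_h: int
    mode: SparsityMode

    def __post_init__(self) -> None:
        if self.d_v < 0 or self.d_h < 0:
            raise ValueError("directional sparsities must be non-negative")


def mlv_map(img: np.ndarray) -> MLVMap:
    """Maximum absolute difference to the 8 neighbors, replicate-padded."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("mlv_map requires an image of at least 3x3")
    padded = np.pad(img, 1, mode="edge")
    out = np.zeros_like(img)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            shifted = padded[1 + di:padded.shape[0] - 1 + di,
                             1 + dj:padded.shape[1] - 1 + dj]
            np.maximum(out, np.abs(img - shifted), out=out)
    return MLVMap(values=out)


def detect_edges(mlv: MLVMap, direction: Direction,
                 threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
                 ) -> np.ndarray:
    """Directional edge-pixel mask of the MLV map.

    A 3x3 Sobel derivative is taken across the stated edge orientation
    ("vertical" edges are intensity transitions along a row, detected by a
    horizontal derivative).  A pixel is an edge pixel when its absolute
    response is a strict local maximum along the scan direction and exceeds
    ``threshold_fraction`` times the global maximum response.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if direction not in ("vertical", "horizontal"):
        raise ValueError(f"unknown direction {direction!r}")
    axis = 1 if direction == "vertical" else 0
    response = np.abs(ndimage.sobel(mlv.values, axis=axis, mode="nearest"))
    peak = response.max()
    mask = np.zeros(response.shape, dtype=bool)
    if peak == 0.0:
        return mask
    threshold = threshold_fraction * peak
    if axis == 1:
        interior, left, right = (response[:, 1:-1], response[:, :-2],
                                 response[:, 2:])
    else:
        interior, left, right = (response[1:-1, :], response[:-2, :],
                                 response[2:, :])
    # local maximum along the scan direction; two-pixel response plateaus
    # (symmetric clean ridges) count on both pixels, which keeps the rule
    # invariant under scan reversal
    local_max = (((interior > left) & (interior >= right))
                 | ((interior >= left) & (interior > right)))
    hit = local_max & (interior > threshold)
    if axis == 1:
        mask[:, 1:-1] = hit
    else:
        mask[1:-1, :] = hit
    return mask


def _scan_to_extremum(profile: np.ndarray, pos: int, step: int
                      ) -> tuple[int, bool]:
    """Index of the nearest local extremum from ``pos`` in direction ``step``.

    The scan continues while the profile is strictly monotone, passes
    through plateaus only if the trend resumes beyond them, and otherwise
    stops at the last strictly-changed index.  Returns (index, truncated).
    """
    n = len(profile)
    i = pos
    j = i + step
    while 0 <= j < n and profile[j] == profile[i]:
        j += step
    if not 0 <= j < n:
        return (0 if step < 0 else n - 1), True
    rising = profile[j] > profile[i]
    prev = j
    k = j + step
    while 0 <= k < n:
        if profile[k] == profile[prev]:
            # plateau: look ahead for trend resumption
            ahead = k + step
            while 0 <= ahead < n and profile[ahead] == profile[prev]:
                ahead += step
            if 0 <= ahead < n and (profile[ahead] > profile[prev]) == rising:
                prev = ahead
                k = ahead + step
                continue
            return prev, False
        if (profile[k] > profile[prev]) == rising:
            prev = k
            k += step
            continue
        return prev, False
    return prev, True


def edge_width(profile: np.ndarray, position: int) -> tuple[int, bool]:
    """Marziliano width of an edge pixel on a 1-D scan-line profile.

    The edge's start and end are the local extrema of the profile nearest
    to ``position`` on either side; the width is their index distance
    (at least 1).  The second element reports whether either search was
    truncated at the line boundary.
    """
    profile = np.asarray(profile, dtype=np.float64)
    start, trunc_left = _scan_to_extremum(profile, position, -1)
    end, trunc_right = _scan_to_extremum(profile, position, +1)
    return max(end - start, 1), trunc_left or trunc_right


def directional_sparsity(mlv: MLVMap, direction: Direction,
                         mode: SparsityMode = DEFAULT_SPARSITY_MODE,
                         threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
                         ) -> tuple[float, int]:
    """Sparsity of edge pixels along one direction; returns (value, n_edges).

    ``width`` mode: sum of Marziliano edge widths over detected edge pixels
    divided by their count.  ``spacing`` mode: the average distance between
    edge pixels, computed as the mean segment length when every scan line
    is cut at its detected edge pixels -- ``n_lines * line_length /
    (n_edges + n_lines)`` -- i.e. the inverse linear density of edge
    pixels.  Zero when no edges are detected.
    """
    mask = detect_edges(mlv, direction, threshold_fraction)
    values = mlv.values
    if direction == "horizontal":
        # scan along columns: transpose so scan lines are rows
        mask = mask.T
        values = values.T
    n_edges = int(mask.sum())
    if n_edges == 0:
        return 0.0, 0
    if mode == "width":
        total = 0
        for row in range(mask.shape[0]):
            cols = np.flatnonzero(mask[row])
            if cols.size == 0:
                continue
            profile = values[row]
            for c in cols:
                w, _ = edge_width(profile, int(c))
                total += w
        return total / n_edges, n_edges
    if mode == "spacing":
        n_lines, length = mask.shape
        return n_lines * length / (n_edges + n_lines), n_edges
    raise ValueError(f"unknown sparsity mode {mode!r}")


def combined_sparsity(d_v: float, d_h: float) -> float:
    """Euclidean combination d = sqrt(d_v^2 + d_h^2)."""
    if d_v < 0 or d_h < 0:
        raise ValueError("directional sparsities must be non-negative")
    return float(np.hypot(d_v, d_h))


def edge_sparsity(img: np.ndarray,
                  mode: SparsityMode = DEFAULT_SPARSITY_MODE,
                  threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
                  ) -> EdgeSparsity:
    """Full directional sparsity analysis of one image (MLV map + both axes)."""
    mlv = mlv_map(img)
    d_v, n_v = directional_sparsity(mlv, "vertical", mode, threshold_fraction)
    d_h, n_h = directional_sparsity(mlv, "horizontal", mode, threshold_fraction)
    return EdgeSparsity(d_v=d_v, d_h=d_h, d=combined_sparsity(d_v, d_h),
                        n_edges_v=n_v, n_edges_h=n_h, mode=mode)
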