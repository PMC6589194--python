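"""Per-image scoring pipeline and fusion of S and d into the quality score Q.

A micrograph is decomposed and only its cartoon component is scored: the
spectral-spatial score S and the MLV edge sparsity d are both computed on
u, since human observers are more sensitive to blur on structural edges
than in redundant texture.  Across a batch the two statistics are max-
normalized and fused,

    Q_i = eta * S_i / max_j S_j + (1 - eta) * d_i / max_j d_j,

with eta = 0.3 by default (the edge term dominates).  Lower S, d and Q all
mean a more blurred micrograph.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from typing import Optional, Sequence

from .cartoon import decompose
from .config import PipelineConfig
from .io import Micrograph, as_canonical
from .mlv import edge_sparsity
from .spatial import spectral_spatial_score

logger = logging.getLogger(__name__)

DEFAULT_ETA = 0.3


@dataclasses.dataclass
class QualityRecord:
    """Per-image metrics: S, d, and (after batch normalization) Q."""

    identifier: str
    S: float
    d: float
    Q: Optional[float] = None
    eta: Optional[float] = None
    d_v: float = 0.0
    d_h: float = 0.0
    n_edges_v: int = 0
    n_edges_h: int = 0
    sparsity_mode: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.S <= 1.0:
            raise ValueError("S must lie in [0, 1]")
        if self.d < 0:
            raise ValueError("d must be non-negative")
        if self.Q is not None and not -1e-12 <= self.Q <= 1.0 + 1e-12:
            raise ValueError("Q must lie in [0, 1]")


class DegenerateBatchError(ValueError):
    """All-zero S or d across a batch: max-normalization is undefined.

    Supply fixed reference normalizers (``max_s_ref``/``max_d_ref`` in the
    config) to score such batches, e.g. single flat frames.
    """


def score_micrograph(img: Micrograph,
                     config: PipelineConfig | None = None) -> QualityRecord:
    """Compute S and d for one micrograph (Q requires batch normalization).

    Pipeline: cartoon-texture decomposition at the configured sigma, then
    on the cartoon component only: spectral-spatial sharpness -> S and MLV
    edge sparsity -> d.  The texture component is discarded for scoring.
    """
    cfg = config or PipelineConfig()
    identifier = img.identifier if isinstance(img, Micrograph) else ""
    pixels = as_canonical(img)

    t0 = time.perf_counter()
    try:
        dec = decompose(pixels, sigma=cfg.sigma, a1=cfg.a1, a2=cfg.a2)
    except Exception as exc:
        raise RuntimeError(f"decomposition stage failed for {identifier!r}") from exc
    t1 = time.perf_counter()
    try:
        sharp = spectral_spatial_score(
            dec.cartoon, block_size=cfg.block_size, step=cfg.step,
            mu=cfg.mu, pool_fraction=cfg.pool_fraction,
            tau1=cfg.tau1, tau2=cfg.tau2)
    except Exception as exc:
        raise RuntimeError(f"sharpness stage failed for {identifier!r}") from exc
    t2 = time.perf_counter()
    try:
        sparsity = edge_sparsity(dec.cartoon, mode=cfg.sparsity_mode,
                                 threshold_fraction=cfg.edge_threshold_fraction)
    except Exception as exc:
        raise RuntimeError(f"edge-sparsity stage failed for {identifier!r}") from exc
    t3 = time.perf_counter()
    logger.info(
        "%s: decompose %.3fs, sharpness %.3fs, sparsity %.3fs (mode=%s)",
        identifier, t1 - t0, t2 - t1, t3 - t2, cfg.sparsity_mode)

    return QualityRecord(
        identifier=identifier, S=sharp.S, d=sparsity.d,
        d_v=sparsity.d_v, d_h=sparsity.d_h,
        n_edges_v=sparsity.n_edges_v, n_edges_h=sparsity.n_edges_h,
        sparsity_mode=cfg.sparsity_mode)


def finalize_scores(records: Sequence[QualityRecord],
                    eta: float = DEFAULT_ETA,
                    max_s_ref: Optional[float] = None,
                    max_d_ref: Optional[float] = None) -> list[QualityRecord]:
    """Max-normalize S and d over the batch and fuse into Q.

    Normalizers default to the batch maxima; fixed reference values may be
    supplied for reproducible single-image scoring.
    """
    if not records:
        raise ValueError("finalize_scores requires at least one record")
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    max_s = max_s_ref if max_s_ref is not None else max(r.S for r in records)
    max_d = max_d_ref if max_d_ref is not None else max(r.d for r in records)
    if max_s <= 0 or max_d <= 0:
        raise DegenerateBatchError(
            "batch maxima of S and d must be positive; supply fixed "
            "reference normalizers to score degenerate batches")
    out = []
    for r in records:
        q = eta * r.S / max_s + (1.0 - eta) * r.d / max_d
        out.append(dataclasses.replace(r, Q=q, eta=eta))
    return out
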