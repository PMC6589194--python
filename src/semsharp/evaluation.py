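"""Agreement between objective scores and opinion scores: PLCC, RMSE, SROCC.

PLCC (Pearson linear correlation) and RMSE are conventionally computed
after mapping the objective scores through a fitted monotone curve that
absorbs the arbitrary scale difference between metric and opinion scale;
SROCC (Spearman rank correlation) is scale-free and always computed on raw
scores.  The mapping used here is the 4-parameter monotone logistic common
in quality-assessment studies,

    x_hat = b1 * (1/2 - 1 / (1 + exp(b2 * (y - b3)))) + b4,

fitted by least squares from several deterministic initializations.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ScorePairing:
    """Paired subjective (x) and objective (y) scores."""

    subjective: np.ndarray
    objective: np.ndarray

    def __post_init__(self) -> None:
        self.subjective = np.asarray(self.subjective, dtype=np.float64)
        self.objective = np.asarray(self.objective, dtype=np.float64)
        if self.subjective.shape != self.objective.shape:
            raise ValueError("subjective and objective lengths differ")
        if self.subjective.ndim != 1 or len(self.subjective) < 3:
            raise ValueError("need at least 3 paired scores")
        if not (np.isfinite(self.subjective).all()
                and np.isfinite(self.objective).all()):
            raise ValueError("scores must be finite")

    @property
    def n(self) -> int:
        return len(self.subjective)


def plcc(pairs: ScorePairing) -> float:
    """Pearson product-moment correlation between the two score sequences."""
    if np.std(pairs.subjective) == 0 or np.std(pairs.objective) == 0:
        raise ValueError("PLCC undefined for zero-variance scores")
    return float(stats.pearsonr(pairs.subjective, pairs.objective).statistic)


def rmse(pairs: ScorePairing) -> float:
    """Root-mean-square error between the two score sequences."""
    diff = pairs.subjective - pairs.objective
    return float(np.sqrt(np.mean(diff ** 2)))


def srocc(pairs: ScorePairing) -> float:
    """Spearman rank correlation via the rank-difference formula.

    1 - 6 * sum((r_x - r_y)^2) / (n * (n^2 - 1)) with average ranks for
    ties.  The formula is exact for tie-free data; with ties it is the
    conventional approximation used throughout the quality-assessment
    literature.
    """
    rx = stats.rankdata(pairs.subjective, method="average")
    ry = stats.rankdata(pairs.objective, method="average")
    n = pairs.n
    return float(1.0 - 6.0 * np.sum((rx - ry) ** 2) / (n * (n * n - 1.0)))


def _logistic4(y: np.ndarray, b1: float, b2: float, b3: float,
               b4: float) -> np.ndarray:
    return b1 * (0.5 - 1.0 / (1.0 + np.exp(np.clip(b2 * (y - b3), -500, 500)))) + b4


def fit_mapping(pairs: ScorePairing) -> np.ndarray:
    """Map objective scores onto the subjective scale via a fitted logistic.

    Least squares over 5 deterministic multi-start initializations; on
    total failure the identity mapping is returned with a logged warning.
    Returns the mapped objective sequence (for PLCC/RMSE use).
    """
    x, y = pairs.subjective, pairs.objective
    if pairs.n < 5:
        raise ValueError("fit_mapping requires at least 5 pairs")
    if np.std(y) == 0:
        raise ValueError("objective scores have zero variance")
    x_span = x.max() - x.min() or 1.0
    y_std = np.std(y)
    starts = [
        (x_span, 1.0 / y_std, float(np.median(y)), float(np.mean(x))),
        (2.0 * x_span, 0.5 / y_std, float(np.mean(y)), float(np.mean(x))),
        (-x_span, 1.0 / y_std, float(np.median(y)), float(np.mean(x))),
        (x_span, 4.0 / y_std, float(np.median(y)), float(np.mean(x))),
        (x_span, 0.1 / y_std, float(np.median(y)), float(np.mean(x))),
    ]
    best_params, best_sse = None, np.inf
    for p0 in starts:
        try:
            params, _ = optimize.curve_fit(_logistic4, y, x, p0=p0,
                                           maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((x - _logistic4(y, *params)) ** 2))
        if sse < best_sse:
            best_sse, best_params = sse, params
    if best_params is None:
        logger.warning("logistic fit failed from every start; "
                       "falling back to the identity mapping")
        return y.copy()
    logger.info("logistic mapping fitted: b=%s, sse=%.3g", best_params, best_sse)
    return _logistic4(y, *best_params)


def evaluate(subjective: Sequence[float],
             objective: Sequence[float]) -> dict:
    """Full agreement report between opinion scores and metric scores.

    Returns PLCC raw and after logistic mapping, RMSE raw and after
    mapping, SROCC (raw only), and n.
    """
    pairs = ScorePairing(np.asarray(subjective), np.asarray(objective))
    mapped = fit_mapping(pairs)
    mapped_pairs = ScorePairing(pairs.subjective, mapped)
    return {
        "plcc_raw": plcc(pairs),
        "plcc_fitted": plcc(mapped_pairs),
        "rmse_raw": rmse(pairs),
        "rmse_fitted": rmse(mapped_pairs),
        "srocc": srocc(pairs),
        "n": pairs.n,
    }
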