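"""Token-level localization metrics, region statistics and model selection.

Attribution quality is measured against token-level ground-truth masks
with AUPRC, thresholded precision / dice / Matthews correlation, and an
average precision over a set of score thresholds.  Region prevalence and
dispersion characterize how hard a mask is to localize.  Hyperparameter
grids are ranked by a sequential (lexicographic) criterion over the four
token metrics averaged on the training set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import average_precision_score

from .errors import InvalidArgumentError, UndefinedMetricError
from .mapgraph import MapGraph

__all__ = [
    "EvalResult",
    "RegionStats",
    "auprc",
    "threshold_metrics",
    "average_precision_thresholds",
    "evaluate_map",
    "region_stats",
    "select_model",
    "macro_mean",
]

DEFAULT_THRESHOLD = 0.0  # fold-change kernels are signed; positive => class 1


@dataclass
class EvalResult:
    """Per-datum localization metrics at a stated threshold."""

    auprc: float
    ap: float
    precision: float
    dice: float
    mcc: float
    threshold: float
    datum_id: str = ""


@dataclass
class RegionStats:
    """Mask geometry: prevalence and dispersion of class-specific regions."""

    prevalence: float
    dispersion: float
    n_components: int
    mean_component_size: float


def _check_mask(scores: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if scores.shape != mask.shape:
        raise InvalidArgumentError("scores and mask must have equal length")
    if not mask.any() or mask.all():
        raise UndefinedMetricError(
            "metrics undefined: mask needs at least one positive and one negative"
        )
    return scores, mask


def auprc(scores: Sequence[float], mask: Sequence[bool]) -> float:
    """Area under the precision-recall curve of scores ranking the mask,
    by the step-wise summation sum_n (R_n - R_{n-1}) P_n."""
    scores, mask = _check_mask(np.asarray(scores), np.asarray(mask))
    return float(average_precision_score(mask.astype(int), scores))


def threshold_metrics(
    scores: Sequence[float],
    mask: Sequence[bool],
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[float, float, float]:
    """(precision, dice, MCC) after binarizing score >= threshold.

    Conventions for empty denominators: 0/0 precision -> 0; MCC with a zero
    denominator -> 0.
    """
    scores, mask = _check_mask(np.asarray(scores), np.asarray(mask))
    pred = scores >= threshold
    tp = float(np.sum(pred & mask))
    fp = float(np.sum(pred & ~mask))
    fn = float(np.sum(~pred & mask))
    tn = float(np.sum(~pred & ~mask))
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return precision, dice, float(mcc)


def average_precision_thresholds(
    scores: Sequence[float],
    mask: Sequence[bool],
    thresholds: Optional[Sequence[float]] = None,
) -> float:
    """Mean precision over a set of score thresholds (0/0 precision -> 0).

    By default the thresholds are the datum's score deciles.  This
    threshold-set AP is reported alongside (and named distinctly from) the
    PR-curve area ``auprc``.
    """
    scores, mask = _check_mask(np.asarray(scores), np.asarray(mask))
    if thresholds is None:
        thresholds = np.quantile(scores, np.linspace(0.1, 1.0, 10))
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise InvalidArgumentError("need at least one threshold")
    precisions = []
    for t in thresholds:
        pred = scores >= t
        tp = float(np.sum(pred & mask))
        fp = float(np.sum(pred & ~mask))
        precisions.append(tp / (tp + fp) if (tp + fp) > 0 else 0.0)
    return float(np.mean(precisions))


def evaluate_map(
    scores: Sequence[float],
    mask: Sequence[bool],
    threshold: float = DEFAULT_THRESHOLD,
    datum_id: str = "",
) -> EvalResult:
    """All token-level metrics for one prospect map against its mask."""
    precision, dice, mcc = threshold_metrics(scores, mask, threshold)
    return EvalResult(
        auprc=auprc(scores, mask),
        ap=average_precision_thresholds(scores, mask),
        precision=precision,
        dice=dice,
        mcc=mcc,
        threshold=threshold,
        datum_id=datum_id,
    )


def region_stats(graph: MapGraph, mask: Sequence[bool]) -> RegionStats:
    """Prevalence (# positive tokens / T) and dispersion (# connected
    components of the mask-induced subgraph / mean component size)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (graph.n_vertices,):
        raise InvalidArgumentError("mask length must equal n_vertices")
    n_pos = int(mask.sum())
    prevalence = n_pos / graph.n_vertices
    if n_pos == 0:
        return RegionStats(0.0, 0.0, 0, 0.0)
    sub = graph.adjacency()[mask][:, mask]
    n_comp, _ = connected_components(sp.csr_matrix(sub), directed=False)
    mean_size = n_pos / n_comp
    return RegionStats(
        prevalence=prevalence,
        dispersion=n_comp / mean_size,
        n_components=int(n_comp),
        mean_component_size=mean_size,
    )


def macro_mean(results: Sequence[EvalResult]) -> dict[str, float]:
    """Macro average (per-datum then mean) of every metric."""
    if not results:
        raise InvalidArgumentError("need at least one result")
    return {
        "precision": float(np.mean([e.precision for e in results])),
        "dice": float(np.mean([e.dice for e in results])),
        "mcc": float(np.mean([e.mcc for e in results])),
        "auprc": float(np.mean([e.auprc for e in results])),
        "ap": float(np.mean([e.ap for e in results])),
    }


def select_model(
    candidates: Sequence[tuple[dict, Sequence[EvalResult]]],
) -> tuple[dict, Sequence[EvalResult]]:
    """Sequential (lexicographic) ranking over macro-averaged training
    metrics: precision, then dice, then MCC, then AUPRC, all descending.
    Remaining ties go to the smallest (K, r), then input order.
    """
    if not candidates:
        raise InvalidArgumentError("need at least one candidate")

    def sort_key(item):
        idx, (hyper, results) = item
        m = macro_mean(results)
        return (
            -m["precision"], -m["dice"], -m["mcc"], -m["auprc"],
            hyper.get("K", 0), hyper.get("r", 0), idx,
        )

    best = min(enumerate(candidates), key=sort_key)
    return best[1]
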