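"""End-to-end fitting and evaluation plumbing.

Thin composition of the two layers: sample a token-embedding pool, fit
the quantizer, roll up sprite embeddings, rescale, fit the kernel
(fold-change or linear), then score data with the kernel convolution and
evaluate against masks.  Used by the command-line interface and directly
from Python.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import InvalidArgumentError
from .k2conv import ProspectMap, batch_prospect
from .kernel import (
    Kernel,
    compute_class_profiles,
    fit_kernel_foldchange,
    fit_kernel_linear,
)
from .mapgraph import MapGraph
from .metrics import EvalResult, evaluate_map, macro_mean, select_model
from .quantizer import (
    DEFAULT_POOL_SIZE,
    Quantizer,
    fit_quantizer,
    quantize,
    sample_pool,
)
from .sprite import rescale_embeddings, rollup

__all__ = ["FittedProspector", "fit_prospector", "evaluate_maps", "tune_grid"]


@dataclass
class FittedProspector:
    quantizer: Quantizer
    kernel: Kernel

    def predict(self, dataset: Sequence[MapGraph]) -> list[ProspectMap]:
        return batch_prospect(dataset, self.quantizer, self.kernel)


def fit_prospector(
    train: Sequence[MapGraph],
    K: int,
    r: int,
    variant: str = "fold_change",
    pool_size: int = DEFAULT_POOL_SIZE,
    seed: int = 0,
    rescale_method: str = "l1",
    alpha: float = 0.05,
    epsilon: float = 1e-6,
    lambda_mix: float = 0.5,
    strength: float = 1.0,
    quantizer: Optional[Quantizer] = None,
) -> FittedProspector:
    """Fit both layers sequentially on labelled training graphs.

    Only datum-level labels are consumed; masks, if present, are ignored
    here (they belong to model selection and evaluation).  Passing a
    pre-fitted ``quantizer`` skips layer-I fitting, which lets a
    hyperparameter sweep over r reuse one codebook per K.
    """
    labels = {g.label for g in train}
    if labels - {0, 1} or len(labels) < 2:
        raise InvalidArgumentError(
            "training data must carry both binary labels (0 and 1)"
        )
    if quantizer is None:
        pool = sample_pool(train, target_size=pool_size, seed=seed)
        quantizer = fit_quantizer(pool, K=K, seed=seed)
    elif quantizer.K != K:
        raise InvalidArgumentError("supplied quantizer has mismatched K")
    embeddings = [rollup(quantize(g, quantizer), r) for g in train]
    rescale_embeddings(embeddings, method=rescale_method)
    if variant == "fold_change":
        profiles = compute_class_profiles(embeddings)
        kernel = fit_kernel_foldchange(
            profiles, embeddings, alpha=alpha, epsilon=epsilon)
    elif variant == "linear":
        kernel = fit_kernel_linear(
            embeddings, lambda_mix=lambda_mix, strength=strength)
    else:
        raise InvalidArgumentError(f"unknown kernel variant {variant!r}")
    return FittedProspector(quantizer=quantizer, kernel=kernel)


def evaluate_maps(
    maps: Sequence[ProspectMap],
    graphs: Sequence[MapGraph],
    threshold: float = 0.0,
) -> list[EvalResult]:
    """Evaluate each map against its graph's mask.

    Graphs with degenerate masks (no positives, or all positives) are
    skipped — attribution metrics are undefined there.
    """
    results = []
    for pmap, g in zip(maps, graphs):
        if g.mask is None or not g.mask.any() or g.mask.all():
            continue
        results.append(evaluate_map(pmap.scores, g.mask,
                                    threshold=threshold,
                                    datum_id=g.datum_id))
    return results


def tune_grid(
    train: Sequence[MapGraph],
    grid: Sequence[dict],
    pool_size: int = DEFAULT_POOL_SIZE,
    seed: int = 0,
    rescale_method: str = "l1",
    threshold: float = 0.0,
) -> tuple[dict, list[tuple[dict, list[EvalResult], dict]]]:
    """Grid search with the sequential ranking criterion.

    Each grid point is a dict with at least K, r, variant (plus variant
    hyperparameters).  Every candidate is fitted on the training data and
    scored against the training masks (which the kernel fit itself never
    sees); candidates are ranked lexicographically by mean precision, dice,
    MCC then AUPRC.  Returns (winning grid point, full report) where the
    report rows are (grid point, per-datum results, macro means).
    """
    if not grid:
        raise InvalidArgumentError("hyperparameter grid is empty")
    quantizer_cache: dict[int, Quantizer] = {}
    candidates = []
    report = []
    for point in grid:
        K = point["K"]
        if K not in quantizer_cache:
            pool = sample_pool(train, target_size=pool_size, seed=seed)
            quantizer_cache[K] = fit_quantizer(pool, K=K, seed=seed)
        fitted = fit_prospector(
            train,
            K=K,
            r=point["r"],
            variant=point.get("variant", "fold_change"),
            pool_size=pool_size,
            seed=seed,
            rescale_method=rescale_method,
            alpha=point.get("alpha", 0.05),
            epsilon=point.get("epsilon", 1e-6),
            lambda_mix=point.get("lambda_mix", 0.5),
            strength=point.get("strength", 1.0),
            quantizer=quantizer_cache[K],
        )
        maps = fitted.predict(train)
        results = evaluate_maps(maps, train, threshold=threshold)
        if not results:
            raise InvalidArgumentError(
                "no training datum has a usable ground-truth mask")
        candidates.append((point, results))
        report.append((point, results, macro_mean(results)))
    best_point, _ = select_model(candidates)
    return best_point, report
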