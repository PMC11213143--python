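"""Layer II fitting: the global kernel over monograms and skip-bigrams.

The kernel is an associative memory — a dictionary mapping each concept
monogram and skip-bigram key to a real class-association weight.  Two
fitting variants are provided: a parameter-free fold-change computation
(log2 ratio of class-mean probabilities, filtered by a two-sample
location test) and an elastic-net logistic regression whose coefficients
become the weights.  Lookup of any unseen key returns 0, so unseen
test-time combinations contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import FitError, InvalidArgumentError
from .sprite import FeatureKey, SpriteEmbedding, n_canonical_keys

__all__ = [
    "Kernel",
    "ClassProfiles",
    "compute_class_profiles",
    "fit_kernel_foldchange",
    "fit_kernel_linear",
    "kernel_lookup",
    "save_kernel",
    "load_kernel",
]

DEFAULT_EPSILON = 1e-6
DEFAULT_ALPHA = 0.05


@dataclass
class Kernel:
    """Dictionary from monogram/bigram keys to class-association weights."""

    weights: dict[FeatureKey, float]
    K: int
    r: int
    variant: str  # "fold_change" | "linear"
    hyperparams: dict = field(default_factory=dict)
    p_values: Optional[dict[FeatureKey, float]] = None

    def __post_init__(self) -> None:
        if self.r < 0:
            raise InvalidArgumentError("r must be non-negative")
        for key, w in self.weights.items():
            if key.max_concept >= self.K:
                raise InvalidArgumentError("kernel key concept out of range")
            if not np.isfinite(w):
                raise InvalidArgumentError("kernel weights must be finite")

    def lookup(self, key: FeatureKey) -> float:
        return kernel_lookup(self, key)

    def n_stored(self) -> int:
        return len(self.weights)

    def mono_vector(self) -> np.ndarray:
        """Monogram weights as a length-K vector (absent keys are 0)."""
        w = np.zeros(self.K)
        for key, val in self.weights.items():
            if key.arity == "mono":
                w[key.c1] = val
        return w

    def bigram_matrix(self) -> np.ndarray:
        """Symmetric K x K matrix of bigram weights (absent keys are 0)."""
        W = np.zeros((self.K, self.K))
        for key, val in self.weights.items():
            if key.arity == "bi":
                W[key.c1, key.c2] = val
                W[key.c2, key.c1] = val
        return W


def kernel_lookup(kernel: Kernel, key: FeatureKey) -> float:
    """Stored weight, or 0 for absent keys; bigram queries are canonicalized."""
    if key.max_concept >= kernel.K:
        raise InvalidArgumentError(
            f"key concept {key.max_concept} >= K={kernel.K}"
        )
    if key.arity == "bi":
        key = FeatureKey.bi(key.c1, key.c2)
    return kernel.weights.get(key, 0.0)


@dataclass
class ClassProfiles:
    """Per-class means of rescaled sprite embeddings (baseline vectors)."""

    mean_class0: dict[FeatureKey, float]
    mean_class1: dict[FeatureKey, float]
    n0: int
    n1: int


def _labelled(embeddings: Sequence[SpriteEmbedding]) -> tuple[list, list]:
    e0 = [e for e in embeddings if e.label == 0]
    e1 = [e for e in embeddings if e.label == 1]
    if not e0 or not e1:
        raise InvalidArgumentError("both classes must be present")
    return e0, e1


def _key_union(embeddings: Sequence[SpriteEmbedding]) -> list[FeatureKey]:
    keys = set()
    for e in embeddings:
        keys.update(e.counts)
    return sorted(keys)


def _design_matrix(
    embeddings: Sequence[SpriteEmbedding], keys: Sequence[FeatureKey]
) -> np.ndarray:
    return np.stack([e.values_for(keys, rescaled=True) for e in embeddings])


def compute_class_profiles(embeddings: Sequence[SpriteEmbedding]) -> ClassProfiles:
    """Per-key arithmetic mean of rescaled values within each class.

    A key absent from a datum contributes 0 to that datum's value.
    """
    e0, e1 = _labelled(embeddings)
    keys = _key_union(embeddings)
    m0 = _design_matrix(e0, keys).mean(axis=0)
    m1 = _design_matrix(e1, keys).mean(axis=0)
    return ClassProfiles(
        mean_class0=dict(zip(keys, m0.tolist())),
        mean_class1=dict(zip(keys, m1.tolist())),
        n0=len(e0),
        n1=len(e1),
    )


def _welch_pvalues(X0: np.ndarray, X1: np.ndarray) -> np.ndarray:
    """Per-column Welch two-sample t-test p-values.

    When both classes are constant for a column scipy yields NaN; that case
    is resolved directly: equal constants are maximally insignificant (p=1),
    different constants maximally significant (p=0).
    """
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(X1, X0, axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (X0.var(axis=0) == 0) & (X1.var(axis=0) == 0)
    if degenerate.any():
        means_differ = X1.mean(axis=0) != X0.mean(axis=0)
        p = p.copy()
        p[degenerate & means_differ] = 0.0
        p[degenerate & ~means_differ] = 1.0
    p = np.where(np.isnan(p), 1.0, p)
    return p


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``alpha``."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    thresholds = alpha * (np.arange(1, m + 1) / m)
    below = p[order] <= thresholds
    reject = np.zeros(m, dtype=bool)
    if below.any():
        cutoff = np.nonzero(below)[0].max()
        reject[order[: cutoff + 1]] = True
    return reject


def fit_kernel_foldchange(
    profiles: ClassProfiles,
    embeddings: Sequence[SpriteEmbedding],
    alpha: float = DEFAULT_ALPHA,
    epsilon: float = DEFAULT_EPSILON,
    bh_correction: bool = False,
) -> Kernel:
    """Fold-change kernel: w = log2(mean1 + eps) - log2(mean0 + eps) per key,
    kept only where a Welch two-sample t-test on per-datum rescaled values
    rejects equal means at level ``alpha`` (the significance filter acts as
    regularization).  ``bh_correction`` applies Benjamini-Hochberg across
    keys before thresholding (off by default).
    """
    if not 0 < alpha < 1:
        raise InvalidArgumentError("alpha must lie in (0, 1)")
    if epsilon <= 0:
        raise InvalidArgumentError("epsilon must be positive")
    e0, e1 = _labelled(embeddings)
    keys = _key_union(embeddings)
    X0 = _design_matrix(e0, keys)
    X1 = _design_matrix(e1, keys)
    m0 = np.array([profiles.mean_class0.get(k, 0.0) for k in keys])
    m1 = np.array([profiles.mean_class1.get(k, 0.0) for k in keys])
    w = np.log2(m1 + epsilon) - np.log2(m0 + epsilon)
    p = _welch_pvalues(X0, X1)
    if bh_correction:
        reject = _benjamini_hochberg(p, alpha)
    else:
        reject = p < alpha
    r = embeddings[0].r
    weights = {k: float(wi) for k, wi, keep in zip(keys, w, reject) if keep}
    pvals = {k: float(pi) for k, pi in zip(keys, p)}
    K = embeddings[0].K
    return Kernel(
        weights=weights,
        K=K,
        r=r,
        variant="fold_change",
        hyperparams={"alpha": alpha, "epsilon": epsilon,
                     "bh_correction": bh_correction},
        p_values=pvals,
    )


def fit_kernel_linear(
    embeddings: Sequence[SpriteEmbedding],
    lambda_mix: float = 0.5,
    strength: float = 1.0,
) -> Kernel:
    """Elastic-net logistic regression kernel.

    Fits h_w(z) = w^T z predicting the datum label from the rescaled sprite
    embedding, with an elastic-net penalty mixing l1 and l2 by
    ``lambda_mix`` (1 = pure lasso) at overall strength ``strength``.  The
    fitted coefficients become the kernel weights; the intercept is fitted
    but excluded from the kernel.  Coefficients are taken as-is since
    embeddings already live on a common probability scale.
    """
    if not 0 <= lambda_mix <= 1:
        raise InvalidArgumentError("lambda_mix must lie in [0, 1]")
    if strength <= 0:
        raise InvalidArgumentError("strength must be positive")
    e0, e1 = _labelled(embeddings)
    keys = _key_union(embeddings)
    X = _design_matrix(list(embeddings), keys)
    y = np.array([e.label for e in embeddings], dtype=int)
    if np.all(X.var(axis=0) == 0):
        raise FitError("degenerate design: all sprite embeddings identical")
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(
        solver="saga",
        l1_ratio=lambda_mix,
        C=1.0 / strength,
        tol=1e-8,
        max_iter=10_000,
        fit_intercept=True,
    )
    try:
        clf.fit(X, y)
    except Exception as exc:  # pragma: no cover - surfaced with context
        raise FitError(f"logistic regression failed: {exc}") from exc
    coefs = clf.coef_.ravel()
    weights = {k: float(c) for k, c in zip(keys, coefs) if c != 0.0}
    return Kernel(
        weights=weights,
        K=embeddings[0].K,
        r=embeddings[0].r,
        variant="linear",
        hyperparams={"lambda_mix": lambda_mix, "strength": strength,
                     "intercept": float(clf.intercept_[0])},
    )


def save_kernel(kernel: Kernel, path: str) -> None:
    """Structured text serialization: metadata block, then one key per line
    in stable sorted order for diffability."""
    with open(path, "w") as fh:
        fh.write(f"# K={kernel.K}\n# r={kernel.r}\n# variant={kernel.variant}\n")
        for hk in sorted(kernel.hyperparams):
            fh.write(f"# hp.{hk}={kernel.hyperparams[hk]}\n")
        fh.write("key_type\tc1\tc2\tweight\tp_value\n")
        for key in sorted(kernel.weights):
            c2 = "" if key.arity == "mono" else str(key.c2)
            pv = ""
            if kernel.p_values is not None and key in kernel.p_values:
                pv = f"{kernel.p_values[key]:.17g}"
            fh.write(f"{key.arity}\t{key.c1}\t{c2}\t{kernel.weights[key]:.17g}\t{pv}\n")


def load_kernel(path: str) -> Kernel:
    meta: dict[str, str] = {}
    weights: dict[FeatureKey, float] = {}
    pvals: dict[FeatureKey, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line and not line.startswith("key_type"):
                arity, c1, c2, w, pv = line.split("\t")
                fk = (FeatureKey.mono(int(c1)) if arity == "mono"
                      else FeatureKey.bi(int(c1), int(c2)))
                weights[fk] = float(w)
                if pv:
                    pvals[fk] = float(pv)
    hyper = {}
    for k, v in meta.items():
        if k.startswith("hp."):
            name = k[3:]
            try:
                hyper[name] = float(v) if "." in v or "e" in v.lower() else int(v)
            except ValueError:
                hyper[name] = v == "True" if v in ("True", "False") else v
    return Kernel(
        weights=weights,
        K=int(meta["K"]),
        r=int(meta["r"]),
        variant=meta.get("variant", "fold_change"),
        hyperparams=hyper,
        p_values=pvals or None,
    )
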