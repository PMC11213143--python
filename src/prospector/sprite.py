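"""Sprite embeddings: the rollup operator and cross-dataset rescaling.

The rollup operator turns a data sprite into a datum-level "bag of
concepts with skips" vector: for every vertex it enumerates the
r-neighborhood and counts each member concept (monograms) and every
unordered pair of distinct member vertices (skip-bigrams), summing over
all T neighborhoods.  Rescaling converts raw counts to probabilities
(l1) or to TF-IDF weights, shared across the training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError
from .quantizer import Sprite

__all__ = ["FeatureKey", "SpriteEmbedding", "rollup", "rescale_embeddings",
           "write_embedding_tsv"]


@dataclass(frozen=True, order=True)
class FeatureKey:
    """A concept monogram or a canonically ordered skip-bigram.

    Bigrams are unordered: ``bi(a, b)`` and ``bi(b, a)`` map to the same
    key, stored with the lower concept first.
    """

    arity: str  # "mono" | "bi"
    c1: int
    c2: int = -1

    def __post_init__(self) -> None:
        if self.arity not in ("mono", "bi"):
            raise InvalidArgumentError(f"unknown arity {self.arity!r}")
        if self.c1 < 0 or (self.arity == "bi" and self.c2 < 0):
            raise InvalidArgumentError("concepts must be non-negative")
        if self.arity == "mono" and self.c2 != -1:
            raise InvalidArgumentError("monogram key takes a single concept")
        if self.arity == "bi" and self.c1 > self.c2:
            raise InvalidArgumentError("bigram key must be canonical (c1 <= c2)")

    @staticmethod
    def mono(c: int) -> "FeatureKey":
        return FeatureKey("mono", int(c))

    @staticmethod
    def bi(a: int, b: int) -> "FeatureKey":
        a, b = int(a), int(b)
        return FeatureKey("bi", min(a, b), max(a, b))

    @property
    def max_concept(self) -> int:
        return max(self.c1, self.c2)

    def __str__(self) -> str:
        if self.arity == "mono":
            return f"mono({self.c1})"
        return f"bi({self.c1},{self.c2})"


def n_canonical_keys(K: int) -> int:
    """Size of the canonical key space: K monograms + K(K+1)/2 bigrams."""
    return K + K * (K + 1) // 2


@dataclass
class SpriteEmbedding:
    """Datum-level counts (and optional rescaled values) over the key space."""

    counts: dict[FeatureKey, float]
    K: int
    r: int
    datum_id: str = ""
    label: Optional[int] = None
    rescaled: Optional[dict[FeatureKey, float]] = None

    def __post_init__(self) -> None:
        for key, v in self.counts.items():
            if v < 0:
                raise InvalidArgumentError("counts must be non-negative")
            if key.max_concept >= self.K:
                raise InvalidArgumentError("key concept out of range for K")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def values_for(self, keys: Sequence[FeatureKey], rescaled: bool = True) -> np.ndarray:
        src = self.rescaled if rescaled else self.counts
        if rescaled and src is None:
            raise InvalidArgumentError(
                f"embedding {self.datum_id!r} has not been rescaled"
            )
        return np.array([src.get(k, 0.0) for k in keys], dtype=float)


def rollup(sprite: Sprite, r: int) -> SpriteEmbedding:
    """Count concept monograms and skip-bigrams over all r-neighborhoods.

    For each vertex v with neighborhood N_r(v) (including v): every member
    concept increments its monogram count and every unordered pair of
    distinct member vertices increments the canonical bigram count.  A
    vertex never pairs with itself.

    Implemented via neighborhood concept histograms: with H the T x K
    matrix of neighborhood histograms, monogram totals are sum_v H[v] and
    bigram totals follow from H^T H (off-diagonal entries count ordered
    cross pairs; the diagonal needs the choose-2 correction).
    """
    if r < 0:
        raise InvalidArgumentError("r must be non-negative")
    g = sprite.topology
    K = sprite.K
    reach = g.reach_matrix(r)  # T x T bool, row v = N_r(v)
    onehot = np.zeros((g.n_vertices, K))
    onehot[np.arange(g.n_vertices), sprite.concepts] = 1.0
    H = reach.astype(np.float64) @ onehot  # neighborhood histograms
    mono = H.sum(axis=0)  # (K,)
    cross = H.T @ H  # sum_v outer(h_v, h_v)
    counts: dict[FeatureKey, float] = {}
    for c in range(K):
        if mono[c] > 0:
            counts[FeatureKey.mono(c)] = float(round(mono[c]))
    for a in range(K):
        same = (cross[a, a] - mono[a]) / 2.0  # sum_v C(h_a, 2)
        if same > 0:
            counts[FeatureKey.bi(a, a)] = float(round(same))
        for b in range(a + 1, K):
            if cross[a, b] > 0:
                counts[FeatureKey.bi(a, b)] = float(round(cross[a, b]))
    return SpriteEmbedding(
        counts=counts,
        K=K,
        r=r,
        datum_id=g.datum_id,
        label=g.label,
    )


def rescale_embeddings(
    embeddings: Sequence[SpriteEmbedding],
    method: str = "l1",
) -> list[SpriteEmbedding]:
    """Populate ``rescaled`` in-place and return the embeddings.

    ``l1``: each datum's counts divided by its total (a probability
    vector over observed keys).  ``tfidf``: term frequency (the l1 value)
    times a smoothed inverse document frequency ln(N / (1 + df)) + 1, then
    re-normalized to sum to 1 per datum.
    """
    if not embeddings:
        raise InvalidArgumentError("need at least one embedding")
    if method not in ("l1", "tfidf"):
        raise InvalidArgumentError(f"unknown rescale method {method!r}")
    for e in embeddings:
        if e.total <= 0:
            raise InvalidArgumentError(
                f"embedding {e.datum_id!r} has zero total count"
            )
    if method == "l1":
        for e in embeddings:
            t = e.total
            e.rescaled = {k: v / t for k, v in e.counts.items()}
        return list(embeddings)
    # tfidf
    n_docs = len(embeddings)
    df: dict[FeatureKey, int] = {}
    for e in embeddings:
        for k in e.counts:
            df[k] = df.get(k, 0) + 1
    idf = {k: np.log(n_docs / (1.0 + d)) + 1.0 for k, d in df.items()}
    for e in embeddings:
        t = e.total
        raw = {k: (v / t) * idf[k] for k, v in e.counts.items()}
        z = sum(raw.values())
        e.rescaled = {k: v / z for k, v in raw.items()}
    return list(embeddings)


def write_embedding_tsv(embedding: SpriteEmbedding, path: str) -> None:
    """Export as TSV ``key_type c1 c2 count rescaled`` (c2 empty for monograms)."""
    with open(path, "w") as fh:
        fh.write(f"# K={embedding.K}\n# r={embedding.r}\n")
        fh.write(f"# datum_id={embedding.datum_id}\n")
        fh.write(f"# label={'' if embedding.label is None else embedding.label}\n")
        fh.write("key_type\tc1\tc2\tcount\trescaled\n")
        for key in sorted(embedding.counts):
            c2 = "" if key.arity == "mono" else str(key.c2)
            resc = ""
            if embedding.rescaled is not None:
                resc = f"{embedding.rescaled.get(key, 0.0):.17g}"
            fh.write(
                f"{key.arity}\t{key.c1}\t{c2}\t{embedding.counts[key]:.17g}\t{resc}\n"
            )
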