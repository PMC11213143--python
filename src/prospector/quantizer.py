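"""Layer I: vector quantization of token embeddings into concepts.

A K-way partition of embedding space is fit on a pooled sample of token
embeddings from the training set (k-means).  Mapping every vertex of a map
graph through the fitted quantizer replaces its d-dimensional embedding
with a single categorical concept, producing a *data sprite* — a mosaic of
concepts with the same topology as the input graph (a compression ratio
of d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .errors import InvalidArgumentError
from .mapgraph import MapGraph

__all__ = [
    "Quantizer",
    "Sprite",
    "fit_quantizer",
    "sample_pool",
    "quantize",
    "save_quantizer",
    "load_quantizer",
    "write_sprite",
]

DEFAULT_POOL_SIZE = 10_000


@dataclass
class Quantizer:
    """Fitted K-way partition of embedding space (concept codebook)."""

    centroids: np.ndarray  # (K, d)
    seed: int
    sample_size: int

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 1:
            raise InvalidArgumentError("centroids must be a K x d matrix, K >= 1")
        if not np.all(np.isfinite(self.centroids)):
            raise InvalidArgumentError("centroids must be finite")

    @property
    def K(self) -> int:
        return int(self.centroids.shape[0])

    @property
    def dim(self) -> int:
        return int(self.centroids.shape[1])

    def assign(self, embeddings: np.ndarray) -> np.ndarray:
        """Nearest-centroid concept for each row; ties broken by lowest index."""
        X = np.asarray(embeddings, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.dim:
            raise InvalidArgumentError(
                f"embedding dim {X.shape[-1] if X.ndim == 2 else '?'} "
                f"!= centroid dim {self.dim}"
            )
        # squared distances; argmin returns the first (lowest) index on ties
        d2 = (
            np.sum(X * X, axis=1, keepdims=True)
            - 2.0 * X @ self.centroids.T
            + np.sum(self.centroids * self.centroids, axis=1)
        )
        return np.argmin(d2, axis=1).astype(np.int64)


@dataclass
class Sprite:
    """A map graph with one categorical concept per vertex."""

    topology: MapGraph
    concepts: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.concepts = np.asarray(self.concepts, dtype=np.int64)
        if self.concepts.shape != (self.topology.n_vertices,):
            raise InvalidArgumentError("concepts length must equal n_vertices")
        if self.concepts.size and (self.concepts.min() < 0 or self.concepts.max() >= self.K):
            raise InvalidArgumentError("concept values must lie in [0, K)")


def sample_pool(
    dataset: Sequence[MapGraph],
    target_size: int = DEFAULT_POOL_SIZE,
    seed: int = 0,
) -> np.ndarray:
    """Uniform without-replacement sample of token embeddings across a dataset.

    All token embeddings of all data are treated as one flat population;
    min(target_size, population) rows are drawn.  Deterministic per seed.
    """
    mats = [g.embeddings for g in dataset if g.embeddings is not None]
    if not mats or sum(m.shape[0] for m in mats) == 0:
        raise InvalidArgumentError("dataset has no token embeddings to sample")
    flat = np.concatenate(mats, axis=0)
    n = flat.shape[0]
    take = min(int(target_size), n)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=take, replace=False)
    return flat[np.sort(idx)]


def fit_quantizer(
    embedding_pool: np.ndarray,
    K: int,
    seed: int = 0,
    n_init: int = 10,
) -> Quantizer:
    """Fit the concept codebook by k-means on a pooled embedding sample.

    Runs ``n_init`` restarts and keeps the lowest-inertia solution;
    deterministic for a fixed seed.  Centroids are re-ordered by their first
    coordinate (then subsequent ones) so concept identities do not depend on
    k-means initialization order.
    """
    X = np.asarray(embedding_pool, dtype=float)
    if K < 1:
        raise InvalidArgumentError("K must be >= 1")
    if X.ndim != 2 or X.shape[0] < K:
        raise InvalidArgumentError("pool must be n x d with n >= K")
    if not np.all(np.isfinite(X)):
        raise InvalidArgumentError("pool must be finite")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed & 0x7FFFFFFF)
    km.fit(X)
    centroids = km.cluster_centers_
    order = np.lexsort(centroids.T[::-1])
    return Quantizer(centroids=centroids[order], seed=seed, sample_size=X.shape[0])


def quantize(graph: MapGraph, q: Quantizer) -> Sprite:
    """Assign each vertex its nearest concept, keeping the topology."""
    if graph.embeddings is None:
        raise InvalidArgumentError(f"graph {graph.datum_id!r} has no embeddings")
    concepts = q.assign(graph.embeddings)
    return Sprite(topology=graph, concepts=concepts, K=q.K)


def save_quantizer(q: Quantizer, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# K={q.K}\n# dim={q.dim}\n# seed={q.seed}\n")
        fh.write(f"# sample_size={q.sample_size}\n")
        for row in q.centroids:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def load_quantizer(path: str) -> Quantizer:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line:
                rows.append([float(v) for v in line.split("\t")])
    return Quantizer(
        centroids=np.array(rows, dtype=float),
        seed=int(meta.get("seed", 0)),
        sample_size=int(meta.get("sample_size", 0)),
    )


def write_sprite(sprite: Sprite, path: str) -> None:
    """Export as TSV ``vertex<TAB>concept`` (0-based)."""
    with open(path, "w") as fh:
        fh.write(f"# K={sprite.K}\n# datum_id={sprite.topology.datum_id}\n")
        fh.write("vertex\tconcept\n")
        for v, c in enumerate(sprite.concepts):
            fh.write(f"{v}\t{c}\n")
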