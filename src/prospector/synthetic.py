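"""Synthetic multiple-instance datasets with planted class-1 regions.

Generates map graphs whose token embeddings come from a Gaussian mixture
over K_true well-separated concept centroids.  Class-0 data draw every
token's concept from a background distribution; class-1 data additionally
carry planted connected regions whose tokens draw from a signal
distribution — realizing the multiple instance assumption (class-1 data
resemble class-0 data except for class-1-specific tokens).  Region
prevalence (fraction of planted tokens) and dispersion (number of
components vs their mean size) are directly controllable, so localization
difficulty can be swept.

All randomness flows from a single seed through numpy SeedSequence
spawning (one child stream per datum), so any datum is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import FeasibilityError, InvalidArgumentError
from .mapgraph import (
    MapGraph,
    build_grid_graph,
    build_pointcloud_graph,
    build_sequence_graph,
    write_embeddings,
    write_graph,
    write_mask,
)
from .metrics import region_stats

__all__ = ["SynthConfig", "SynthDatum", "plant_regions", "generate_dataset",
           "write_dataset", "read_dataset"]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe the reference setting used throughout: 50 data per
    class on a 20x20 8-way grid (400 tokens, so planted regions of ~20
    tokens have interiors that dominate their boundaries), K_true=5
    concepts on an orthogonal frame separated by 6.0 against isotropic
    noise of sd 0.5 (separation far above noise, so concepts are
    recoverable), background uniform over the first K_true-1 concepts, a
    dominant disjoint signal concept at rate 0.9 inside planted regions,
    prevalence 0.1 split over 2 compact regions.
    """

    n_class0: int = 50
    n_class1: int = 50
    graph_kind: str = "grid"  # sequence | grid | pointcloud
    graph_params: dict = field(default_factory=lambda: {
        "rows": 20, "cols": 20, "connectivity": 8})
    K_true: int = 5
    embed_dim: int = 8
    concept_centroid_separation: float = 6.0
    noise_sd: float = 0.5
    background_concept_probs: Optional[np.ndarray] = None
    signal_concept_probs: Optional[np.ndarray] = None
    prevalence: float = 0.1
    n_regions: int = 2
    region_mode: str = "compact"  # compact | scatter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_class0 < 0 or self.n_class1 < 0:
            raise InvalidArgumentError("class sizes must be non-negative")
        if self.graph_kind not in ("sequence", "grid", "pointcloud"):
            raise InvalidArgumentError(f"unknown graph_kind {self.graph_kind!r}")
        if self.K_true < 2:
            raise InvalidArgumentError("K_true must be >= 2")
        if self.embed_dim < self.K_true:
            raise InvalidArgumentError(
                "embed_dim must be >= K_true for the orthogonal centroid frame"
            )
        if not 0 < self.prevalence < 1:
            raise InvalidArgumentError("prevalence must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise InvalidArgumentError("noise_sd must be positive")
        if self.n_regions < 1:
            raise InvalidArgumentError("n_regions must be positive")
        K = self.K_true
        if self.background_concept_probs is None:
            p = np.zeros(K)
            p[: K - 1] = 1.0 / (K - 1)
            self.background_concept_probs = p
        else:
            self.background_concept_probs = np.asarray(
                self.background_concept_probs, dtype=float)
        if self.signal_concept_probs is None:
            p = np.full(K, 0.1 / (K - 1))
            p[K - 1] = 0.9
            self.signal_concept_probs = p
        else:
            self.signal_concept_probs = np.asarray(
                self.signal_concept_probs, dtype=float)
        for name, p in (("background", self.background_concept_probs),
                        ("signal", self.signal_concept_probs)):
            if p.shape != (K,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise InvalidArgumentError(
                    f"{name}_concept_probs must be a simplex vector over K_true"
                )


@dataclass
class SynthDatum:
    """One generated datum: graph with embeddings, mask and label, plus the
    generating (true) concept of every vertex."""

    graph: MapGraph
    true_concepts: np.ndarray


def _adjacency_lists(graph: MapGraph) -> list[np.ndarray]:
    adj = graph.adjacency()
    return [adj.indices[adj.indptr[v]: adj.indptr[v + 1]]
            for v in range(graph.n_vertices)]


def plant_regions(
    graph: MapGraph,
    n_positive: int,
    n_regions: int,
    seed: int,
    mode: str = "compact",
    max_retries: int = 50,
) -> np.ndarray:
    """Plant exactly ``n_positive`` vertices in exactly ``n_regions``
    connected components.

    Regions are grown round-robin from randomly chosen pairwise
    non-adjacent roots; a vertex joins a region only if it has no neighbor
    in a different region, so components can never merge.  ``compact``
    grows breadth-first with randomized frontier order (blob-like regions);
    ``scatter`` expands from a uniformly random frontier vertex
    (random-walk-like, higher-dispersion shapes).  Deterministic per seed;
    raises after ``max_retries`` infeasible attempts.
    """
    T = graph.n_vertices
    if not 1 <= n_positive <= T:
        raise InvalidArgumentError("n_positive must lie in [1, T]")
    if not 1 <= n_regions <= n_positive:
        raise InvalidArgumentError("need 1 <= n_regions <= n_positive")
    if mode not in ("compact", "scatter"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    neighbors = _adjacency_lists(graph)

    for _ in range(max_retries):
        # greedy pairwise non-adjacent roots from a random permutation
        roots: list[int] = []
        taken = np.zeros(T, dtype=bool)
        for v in rng.permutation(T):
            if not taken[v]:
                roots.append(int(v))
                taken[v] = True
                taken[neighbors[v]] = True
                if len(roots) == n_regions:
                    break
        if len(roots) < n_regions:
            continue
        assign = np.full(T, -1, dtype=np.int64)
        for g_id, root in enumerate(roots):
            assign[root] = g_id
        frontiers: list[list[int]] = []
        for g_id, root in enumerate(roots):
            nb = list(neighbors[root])
            rng.shuffle(nb)
            frontiers.append(nb)
        total = n_regions
        active = list(range(n_regions))
        while total < n_positive and active:
            for g_id in list(active):
                if total >= n_positive:
                    break
                placed = False
                frontier = frontiers[g_id]
                while frontier:
                    if mode == "scatter":
                        pos = int(rng.integers(len(frontier)))
                        u = frontier.pop(pos)
                    else:
                        u = frontier.pop(0)
                    if assign[u] != -1:
                        continue
                    if any(assign[w] not in (-1, g_id) for w in neighbors[u]):
                        continue  # would touch another region
                    assign[u] = g_id
                    total += 1
                    nb = list(neighbors[u])
                    rng.shuffle(nb)
                    frontier.extend(nb)
                    placed = True
                    break
                if not placed:
                    active.remove(g_id)
        if total == n_positive:
            mask = assign >= 0
            stats = region_stats(graph, mask)
            if stats.n_components == n_regions and int(mask.sum()) == n_positive:
                return mask
    raise FeasibilityError(
        f"could not place {n_positive} positives in {n_regions} disjoint "
        f"regions after {max_retries} attempts"
    )


def _centroids(config: SynthConfig) -> np.ndarray:
    """K_true centroids on a scaled orthogonal frame.

    e_k * sep / sqrt(2) gives every pair exact Euclidean distance ``sep``
    in any embed_dim >= K_true.
    """
    C = np.zeros((config.K_true, config.embed_dim))
    scale = config.concept_centroid_separation / np.sqrt(2.0)
    for k in range(config.K_true):
        C[k, k] = scale
    return C


def _build_topology(config: SynthConfig, rng: np.random.Generator) -> MapGraph:
    p = config.graph_params
    if config.graph_kind == "sequence":
        return build_sequence_graph(p.get("n_tokens", 100), p.get("hops", 2))
    if config.graph_kind == "grid":
        return build_grid_graph(p.get("rows", 10), p.get("cols", 10),
                                p.get("connectivity", 8))
    # pointcloud: uniform points in a cubic box; density set by box side
    n = p.get("n_points", 100)
    cutoff = p.get("cutoff", 8.0)
    box = p.get("box", 33.0)
    coords = rng.uniform(0.0, box, size=(n, 3))
    return build_pointcloud_graph(coords, cutoff)


def generate_dataset(config: SynthConfig) -> list[SynthDatum]:
    """Generate ``n_class0 + n_class1`` data under the configured conditions.

    Class-0 data have all-false masks; class-1 data carry
    round(prevalence * T) planted vertices in ``n_regions`` components.
    Every vertex draws its concept from the background distribution
    (planted vertices: from the signal distribution) and its embedding as
    centroid(concept) + N(0, noise_sd^2 I).
    """
    centroids = _centroids(config)
    n_total = config.n_class0 + config.n_class1
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    data: list[SynthDatum] = []
    for i in range(n_total):
        label = 0 if i < config.n_class0 else 1
        rng = np.random.default_rng(children[i])
        graph = _build_topology(config, rng)
        T = graph.n_vertices
        if label == 1:
            n_pos = int(round(config.prevalence * T))
            n_pos = max(n_pos, config.n_regions)
            mask = plant_regions(
                graph, n_pos, config.n_regions,
                seed=int(rng.integers(2**31)), mode=config.region_mode,
            )
        else:
            mask = np.zeros(T, dtype=bool)
        concepts = rng.choice(config.K_true, size=T,
                              p=config.background_concept_probs)
        if mask.any():
            concepts[mask] = rng.choice(config.K_true, size=int(mask.sum()),
                                        p=config.signal_concept_probs)
        emb = centroids[concepts] + rng.normal(0.0, config.noise_sd,
                                               size=(T, config.embed_dim))
        datum = graph.with_fields(
            embeddings=emb, mask=mask, label=label,
            datum_id=f"class{label}_{i:04d}",
        )
        data.append(SynthDatum(graph=datum, true_concepts=concepts))
    return data


def write_dataset(data: list[SynthDatum], outdir: str) -> None:
    """Write graph/embedding/mask files plus a manifest TSV."""
    import os

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for d in data:
        g = d.graph
        write_graph(g, os.path.join(outdir, f"{g.datum_id}.graph.tsv"))
        write_embeddings(g.embeddings,
                         os.path.join(outdir, f"{g.datum_id}.emb.tsv"))
        write_mask(g.mask, os.path.join(outdir, f"{g.datum_id}.mask.tsv"))
        stats = region_stats(g, g.mask)
        rows.append((g.datum_id, g.label, stats.prevalence, stats.dispersion))
    with open(os.path.join(outdir, "manifest.tsv"), "w") as fh:
        fh.write("datum_id\tlabel\tprevalence\tdispersion\n")
        for datum_id, label, prev, disp in rows:
            fh.write(f"{datum_id}\t{label}\t{prev:.17g}\t{disp:.17g}\n")


def read_dataset(indir: str) -> list[MapGraph]:
    """Load the graphs written by :func:`write_dataset`, in manifest order."""
    import os

    from .mapgraph import read_embeddings, read_graph, read_mask

    manifest = os.path.join(indir, "manifest.tsv")
    if not os.path.exists(manifest):
        raise InvalidArgumentError(f"no manifest.tsv in {indir}")
    graphs = []
    with open(manifest) as fh:
        next(fh)  # header
        for line in fh:
            datum_id = line.split("\t")[0]
            g = read_graph(os.path.join(indir, f"{datum_id}.graph.tsv"))
            emb_path = os.path.join(indir, f"{datum_id}.emb.tsv")
            if os.path.exists(emb_path):
                g = g.with_fields(embeddings=read_embeddings(emb_path))
            mask_path = os.path.join(indir, f"{datum_id}.mask.tsv")
            if os.path.exists(mask_path):
                g = g.with_fields(mask=read_mask(mask_path, g.n_vertices))
            graphs.append(g)
    return graphs
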