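"""Map graphs: tokenized data as graphs.

A datum (document, image, protein structure, ...) is represented as a graph
whose vertices are tokens (sentences, patches, residues) and whose edges
encode sequential or spatial adjacency.  Token embeddings and token-level
ground-truth masks attach to vertices.  Vertex indices are 0-based
everywhere, including in serialized files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import scipy.sparse as sp

from .errors import InvalidArgumentError

__all__ = [
    "MapGraph",
    "build_sequence_graph",
    "build_grid_graph",
    "build_pointcloud_graph",
    "neighborhood",
    "write_graph",
    "read_graph",
    "write_mask",
    "read_mask",
    "write_embeddings",
    "read_embeddings",
]


def _canonical_edges(edges: Iterable[tuple[int, int]] | np.ndarray) -> np.ndarray:
    """Return edges as a (m, 2) int array with i < j, lexicographically sorted."""
    arr = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges,
                     dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    arr = arr.reshape(-1, 2)
    lo = arr.min(axis=1)
    hi = arr.max(axis=1)
    arr = np.stack([lo, hi], axis=1)
    arr = np.unique(arr, axis=0)
    return arr


@dataclass
class MapGraph:
    """A tokenized datum: vertices are tokens, edges encode adjacency.

    Parameters
    ----------
    n_vertices
        Number of tokens T.
    edges
        Unordered vertex-index pairs; stored canonically with i < j,
        deduplicated, self-loops rejected.
    embeddings
        Optional T x d matrix of token embeddings (one row per vertex).
    mask
        Optional boolean vector of length T marking class-specific tokens;
        used only for model selection and evaluation, never for fitting.
    datum_id
        Identifier of the datum.
    label
        Optional datum-level binary class label.
    """

    n_vertices: int
    edges: np.ndarray
    embeddings: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    datum_id: str = ""
    label: Optional[int] = None
    _adj: Optional[sp.csr_matrix] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_vertices < 1:
            raise InvalidArgumentError("n_vertices must be positive")
        self.edges = _canonical_edges(self.edges)
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_vertices:
                raise InvalidArgumentError("edge endpoint out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise InvalidArgumentError("self-loop edges are not allowed")
        if self.embeddings is not None:
            self.embeddings = np.asarray(self.embeddings, dtype=float)
            if self.embeddings.ndim != 2 or self.embeddings.shape[0] != self.n_vertices:
                raise InvalidArgumentError(
                    f"embeddings must have {self.n_vertices} rows"
                )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_vertices,):
                raise InvalidArgumentError("mask length must equal n_vertices")

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def adjacency(self) -> sp.csr_matrix:
        """Boolean symmetric adjacency matrix in CSR form (cached)."""
        if self._adj is None:
            T = self.n_vertices
            if self.edges.size:
                i, j = self.edges[:, 0], self.edges[:, 1]
                data = np.ones(2 * len(i), dtype=bool)
                adj = sp.coo_matrix(
                    (data, (np.concatenate([i, j]), np.concatenate([j, i]))),
                    shape=(T, T),
                ).tocsr()
            else:
                adj = sp.csr_matrix((T, T), dtype=bool)
            self._adj = adj
        return self._adj

    def reach_matrix(self, r: int) -> sp.csr_matrix:
        """Boolean T x T matrix with (v, u) True iff hop-distance(v, u) <= r.

        Row v enumerates the r-neighborhood of v (always includes v itself).
        """
        if r < 0:
            raise InvalidArgumentError("r must be non-negative")
        T = self.n_vertices
        reach = sp.identity(T, dtype=bool, format="csr")
        if r == 0:
            return reach
        step = self.adjacency() + sp.identity(T, dtype=bool, format="csr")
        for _ in range(r):
            reach = (reach @ step).astype(bool)
        reach.sort_indices()
        return reach

    def with_fields(self, **kwargs) -> "MapGraph":
        """Copy of this graph with some fields replaced (topology shared)."""
        out = MapGraph(
            n_vertices=self.n_vertices,
            edges=self.edges,
            embeddings=kwargs.get("embeddings", self.embeddings),
            mask=kwargs.get("mask", self.mask),
            datum_id=kwargs.get("datum_id", self.datum_id),
            label=kwargs.get("label", self.label),
        )
        out._adj = self._adj
        return out


def build_sequence_graph(n_tokens: int, hops: int = 2) -> MapGraph:
    """Sequence topology: edge {i, j} iff 0 < |i - j| <= hops.

    ``hops=2`` reproduces the 2-hop connectivity convention for sentence
    sequences.
    """
    if n_tokens < 1 or hops < 1:
        raise InvalidArgumentError("n_tokens and hops must be positive")
    edges = [
        (i, j)
        for i in range(n_tokens)
        for j in range(i + 1, min(i + hops + 1, n_tokens))
    ]
    return MapGraph(n_tokens, np.array(edges, dtype=np.int64).reshape(-1, 2))


def build_grid_graph(
    rows: int,
    cols: int,
    connectivity: int = 8,
    keep: Optional[np.ndarray] = None,
) -> MapGraph:
    """Image-grid topology with rook (4-way) or rook+diagonal (8-way) adjacency.

    Cells are enumerated in row-major order.  ``keep`` (length rows*cols)
    selects foreground cells (e.g. a tissue mask); vertices are the kept
    cells, re-indexed densely in row-major order, and an edge survives only
    when both endpoints are kept.
    """
    if rows < 1 or cols < 1:
        raise InvalidArgumentError("rows and cols must be positive")
    if connectivity not in (4, 8):
        raise InvalidArgumentError("connectivity must be 4 or 8")
    n_cells = rows * cols
    if keep is None:
        keep_arr = np.ones(n_cells, dtype=bool)
    else:
        keep_arr = np.asarray(keep, dtype=bool)
        if keep_arr.shape != (n_cells,):
            raise InvalidArgumentError("keep must have rows*cols entries")
        if not keep_arr.any():
            raise InvalidArgumentError("keep must retain at least one cell")
    new_index = np.full(n_cells, -1, dtype=np.int64)
    new_index[keep_arr] = np.arange(int(keep_arr.sum()))
    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    edges = []
    for rr in range(rows):
        for cc in range(cols):
            a = rr * cols + cc
            if not keep_arr[a]:
                continue
            for dr, dc in offsets:
                r2, c2 = rr + dr, cc + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    b = r2 * cols + c2
                    if keep_arr[b]:
                        edges.append((new_index[a], new_index[b]))
    return MapGraph(int(keep_arr.sum()), np.array(edges, dtype=np.int64).reshape(-1, 2))


def build_pointcloud_graph(coords: np.ndarray, cutoff: float) -> MapGraph:
    """Point-cloud topology: edge {i, j} iff Euclidean distance <= cutoff.

    One coordinate row per token (e.g. a representative atom per residue);
    distances in the units of ``coords`` (angstroms for protein structures).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2:
        raise InvalidArgumentError("coords must be a T x ndim matrix")
    if not np.all(np.isfinite(coords)):
        raise InvalidArgumentError("coordinates must be finite")
    if cutoff <= 0:
        raise InvalidArgumentError("cutoff must be positive")
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    g = MapGraph(coords.shape[0], pairs.astype(np.int64).reshape(-1, 2))
    return g


def neighborhood(graph: MapGraph, vertex: int, r: int) -> set[int]:
    """Vertices at hop distance <= r from ``vertex`` (including itself)."""
    if not 0 <= vertex < graph.n_vertices:
        raise IndexError(f"vertex {vertex} out of range [0, {graph.n_vertices})")
    if r < 0:
        raise InvalidArgumentError("r must be non-negative")
    reach = graph.reach_matrix(r)
    row = reach.indices[reach.indptr[vertex]: reach.indptr[vertex + 1]]
    return set(int(u) for u in row)


# ---------------------------------------------------------------------------
# Serialization: TSV edge list with a '#'-prefixed header; mask as one
# positive vertex index per line; embeddings as a dense whitespace table.

def write_graph(graph: MapGraph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_vertices={graph.n_vertices}\n")
        fh.write(f"# datum_id={graph.datum_id}\n")
        fh.write(f"# label={'' if graph.label is None else int(graph.label)}\n")
        fh.write("# indexing=0-based\n")
        fh.write("src\tdst\n")
        for i, j in graph.edges:
            fh.write(f"{i}\t{j}\n")


def read_graph(path: str) -> MapGraph:
    meta: dict[str, str] = {}
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line and line != "src\tdst":
                i, j = line.split("\t")
                edges.append((int(i), int(j)))
    label_s = meta.get("label", "")
    return MapGraph(
        n_vertices=int(meta["n_vertices"]),
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        datum_id=meta.get("datum_id", ""),
        label=int(label_s) if label_s != "" else None,
    )


def write_mask(mask: np.ndarray, path: str) -> None:
    idx = np.flatnonzero(np.asarray(mask, dtype=bool))
    with open(path, "w") as fh:
        for i in idx:
            fh.write(f"{i}\n")


def read_mask(path: str, n_vertices: int) -> np.ndarray:
    mask = np.zeros(n_vertices, dtype=bool)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                mask[int(line)] = True
    return mask


def write_embeddings(embeddings: np.ndarray, path: str) -> None:
    np.savetxt(path, np.asarray(embeddings, dtype=float), fmt="%.17g", delimiter="\t")


def read_embeddings(path: str) -> np.ndarray:
    arr = np.loadtxt(path, dtype=float, delimiter="\t", ndmin=2)
    return arr
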