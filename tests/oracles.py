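"""Independent brute-force reference implementations.

These deliberately avoid the package's vectorized paths: neighborhoods by
dictionary BFS, counts by explicit double loops over member vertices.
They exist only to check the real implementation on small instances.
"""

from collections import deque

import numpy as np


def adjacency_dict(n_vertices, edges):
    adj = {v: set() for v in range(n_vertices)}
    for i, j in edges:
        adj[int(i)].add(int(j))
        adj[int(j)].add(int(i))
    return adj


def bfs_neighborhood(adj, vertex, r):
    """Vertices at hop distance <= r, by explicit BFS."""
    dist = {vertex: 0}
    queue = deque([vertex])
    while queue:
        u = queue.popleft()
        if dist[u] == r:
            continue
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                queue.append(w)
    return set(dist)


def naive_rollup(n_vertices, edges, concepts, r):
    """Monogram and canonical-bigram counts over all r-neighborhoods."""
    adj = adjacency_dict(n_vertices, edges)
    mono = {}
    bi = {}
    for v in range(n_vertices):
        members = sorted(bfs_neighborhood(adj, v, r))
        for u in members:
            c = int(concepts[u])
            mono[c] = mono.get(c, 0) + 1
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                ca = int(concepts[members[a_idx]])
                cb = int(concepts[members[b_idx]])
                key = (min(ca, cb), max(ca, cb))
                bi[key] = bi.get(key, 0) + 1
    return mono, bi


def naive_k2conv(n_vertices, edges, concepts, r, mono_w, bi_w):
    """Per-vertex scores by explicit neighborhood and pair enumeration.

    ``mono_w``: dict concept -> weight; ``bi_w``: dict (lo, hi) -> weight.
    """
    adj = adjacency_dict(n_vertices, edges)
    scores = np.zeros(n_vertices)
    for v in range(n_vertices):
        members = sorted(bfs_neighborhood(adj, v, r))
        s = 0.0
        for u in members:
            s += mono_w.get(int(concepts[u]), 0.0)
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                ca = int(concepts[members[a_idx]])
                cb = int(concepts[members[b_idx]])
                s += bi_w.get((min(ca, cb), max(ca, cb)), 0.0)
        scores[v] = s
    return scores


def random_instance(rng, kind=None, K=5):
    """A small random map graph of any of the three kinds plus concepts."""
    import prospector as pr

    kind = kind or rng.choice(["sequence", "grid", "pointcloud"])
    if kind == "sequence":
        g = pr.build_sequence_graph(int(rng.integers(1, 50)),
                                    int(rng.integers(1, 4)))
    elif kind == "grid":
        rows = int(rng.integers(1, 8))
        cols = int(rng.integers(1, 50 // rows + 1))
        g = pr.build_grid_graph(rows, cols, int(rng.choice([4, 8])))
    else:
        T = int(rng.integers(2, 50))
        coords = rng.uniform(0, 5, size=(T, 3))
        g = pr.build_pointcloud_graph(coords, float(rng.uniform(0.5, 3.0)))
    concepts = rng.integers(0, K, size=g.n_vertices)
    return g, concepts
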