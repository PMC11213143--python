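"""Layer II inference: kernel convolution producing prospect maps.

Every vertex v of a sprite is scored by summing the kernel weight of each
concept monogram in its r-neighborhood (including v itself) and of every
unordered pair of distinct member vertices (skip-bigrams).  The receptive
field r controls smoothing: larger r mixes more neighboring tokens into
each score.  Positive scores mark class-1-associated tokens under the
fold-change kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError, ProspectorError
from .kernel import Kernel
from .mapgraph import MapGraph
from .quantizer import Quantizer, Sprite, quantize

__all__ = ["ProspectMap", "k2conv", "batch_prospect", "write_prospect_map"]


@dataclass
class ProspectMap:
    """Per-vertex continuous attribution scores on a map-graph topology."""

    topology: MapGraph
    scores: np.ndarray
    r: int
    datum_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (self.topology.n_vertices,):
            raise InvalidArgumentError("scores length must equal n_vertices")
        if not np.all(np.isfinite(self.scores)):
            raise InvalidArgumentError("scores must be finite")


def k2conv(sprite: Sprite, kernel: Kernel, normalize: bool = False) -> ProspectMap:
    """Convolve the kernel over every r-neighborhood of the sprite.

    score(v) = sum_{u in N_r(v)} w_mono(c_u)
             + sum_{unordered pairs {u, w} in N_r(v), u != w} w_bi(c_u, c_w)

    Computed from neighborhood concept histograms: with h the histogram of
    N_r(v) and W the symmetric bigram-weight matrix, the pair term equals
    (h^T W h - sum_a h_a W_aa) / 2.  ``normalize`` divides each score by
    |N_r(v)| (off by default; r itself tunes smoothing).
    """
    if sprite.K != kernel.K:
        raise InvalidArgumentError(
            f"sprite K={sprite.K} does not match kernel K={kernel.K}"
        )
    g = sprite.topology
    reach = g.reach_matrix(kernel.r)
    onehot = np.zeros((g.n_vertices, sprite.K))
    onehot[np.arange(g.n_vertices), sprite.concepts] = 1.0
    H = reach.astype(np.float64) @ onehot  # T x K neighborhood histograms
    w_mono = kernel.mono_vector()
    W = kernel.bigram_matrix()
    mono_term = H @ w_mono
    quad = np.einsum("ij,ij->i", H @ W, H)
    diag_corr = H @ np.diag(W)
    scores = mono_term + 0.5 * (quad - diag_corr)
    if normalize:
        sizes = H.sum(axis=1)
        scores = scores / np.maximum(sizes, 1.0)
    return ProspectMap(topology=g, scores=scores, r=kernel.r,
                       datum_id=g.datum_id)


def batch_prospect(
    dataset: Sequence[MapGraph],
    q: Quantizer,
    kernel: Kernel,
    normalize: bool = False,
) -> list[ProspectMap]:
    """Quantize then convolve each datum, preserving order."""
    maps = []
    for graph in dataset:
        try:
            maps.append(k2conv(quantize(graph, q), kernel, normalize=normalize))
        except ProspectorError as exc:
            raise type(exc)(f"datum {graph.datum_id!r}: {exc}") from exc
    return maps


def write_prospect_map(
    pmap: ProspectMap,
    path: str,
    grid_dims: Optional[tuple[int, int]] = None,
) -> None:
    """Export as TSV ``vertex<TAB>score``; with ``grid_dims`` (rows, cols) a
    full grid is exported as ``row<TAB>col<TAB>score`` in row-major order."""
    with open(path, "w") as fh:
        fh.write(f"# datum_id={pmap.datum_id}\n# r={pmap.r}\n")
        if grid_dims is None:
            fh.write("vertex\tscore\n")
            for v, s in enumerate(pmap.scores):
                fh.write(f"{v}\t{s:.17g}\n")
        else:
            rows, cols = grid_dims
            if rows * cols != pmap.topology.n_vertices:
                raise InvalidArgumentError("grid_dims do not match vertex count")
            fh.write("row\tcol\tscore\n")
            for v, s in enumerate(pmap.scores):
                fh.write(f"{v // cols}\t{v % cols}\t{s:.17g}\n")
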