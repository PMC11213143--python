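# Methods note

## Model

A datum is a map graph `G(V, E)` over tokens with embeddings
`x_v ∈ R^d` produced by any frozen encoder, plus a binary datum label.
The attribution head is:

1. **Quantizer (Layer I).** k-means with `K` clusters fitted on a pooled
   subsample of token embeddings across the training data; each token is
   assigned its nearest centroid's concept ID. The quantized datum (a
   "data sprite") keeps the graph topology but replaces each embedding
   with a categorical concept.
2. **Rollup.** For hop radius `r`, each vertex's neighborhood
   `N_r(v) = {u : hop(u, v) ≤ r}` (self included) contributes one
   monogram count per member and one unordered skip-bigram count per pair
   of distinct members. Summing over all vertices gives the datum's
   sprite embedding `z`, a vector over the `K + K(K+1)/2` canonical keys.
   Embeddings are rescaled before fitting (`l1` by default, so each datum
   is a frequency distribution over keys; `tfidf` is available).
3. **Kernel (Layer II).** A global dictionary `w` from keys to weights,
   fitted on the rescaled embeddings and datum labels. `fold_change`:
   `w(k) = log2(z̄₁(k)+ε) − log2(z̄₀(k)+ε)` where `z̄_y` is the class-`y`
   mean, stored only for keys where a Welch two-sample t-test rejects
   equal class means at level `α`; absent keys read as 0. `linear`:
   elastic-net logistic regression coefficients (intercept fitted but
   excluded).
4. **K²conv scoring.** `score(v)` sums kernel weights of every monogram
   and unordered pair within `N_r(v)`. Vectorized per datum as
   `H w_mono + ½(diag(H W Hᵀ) − H diag(W))` where `H` is the matrix of
   neighborhood concept histograms and `W` the symmetric bigram-weight
   matrix; this is algebraically identical to the pairwise definition.

### Assumptions

- Class signal is expressible as a shift in the *frequency* of concepts
  and local concept co-occurrences; the head cannot represent signals
  that require token order beyond `r` hops or continuous embedding
  directions orthogonal to the concept partition.
- The same kernel applies to every datum (a single global mechanism),
  and token neighborhoods are exchangeable given their concept content.
- Labels are datum-level and binary; class-1 data contain the signal.

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| `K` (concepts) | caller-supplied | task-dependent; `tune_grid` / `prospector tune` select it lexicographically (precision, Dice, MCC, AUPRC; ties to smallest `(K, r)`) |
| `r` (hop radius) | caller-supplied (1 in examples) | r=1 captures immediate co-occurrence; larger r smooths maps and blurs small regions |
| `pool_size` | 10 000 | k-means cost is linear in pool size; 10 000 points estimate ≤ a few dozen centroids stably while keeping fits sub-second |
| rescale | `l1` | puts data of different sizes on a common probability scale, which the fold-change and its ε make sense of |
| `alpha` | 0.05 | conventional test level; it is the only regularizer of the fold-change variant, and its calibration on null data is verified by the test suite and acceptance script |
| `epsilon` | 1e-6 | pseudocount well below any realized l1 frequency of interest; bounds the log-fold-change magnitude for absent keys instead of producing ±∞ |
| `bh_correction` | off | the per-key test is the method's own regularizer; FDR control across keys is offered but not imposed |
| `lambda_mix` | 0.5 | balanced elastic net: l1 sparsity plus l2 stability among correlated keys |
| `strength` | 1.0 | unit penalty; sensible on l1-rescaled (bounded) features |
| score normalization | off | raw scores keep the additive kernel semantics; optional division by `|N_r(v)|` corrects boundary-degree effects when wanted |
| threshold (binary metrics) | 0.0 | the natural decision point of a log-fold-change score: positive means class-1-associated neighborhood evidence |

## Synthetic generator

Each datum is a graph (default: 20×20 grid, 8-connected) whose tokens
draw a latent concept and then an embedding from an isotropic Gaussian
(`noise_sd = 0.5`) around that concept's centroid; centroids sit on an
orthogonal frame scaled so every pairwise distance equals
`concept_centroid_separation = 6.0`. Background tokens draw uniformly
from the first `K_true − 1 = 4` concepts. Class-1 data receive planted
regions (prevalence 0.1, 2 regions, "compact" growth by round-robin BFS
from non-adjacent roots; "scatter" grows from random frontiers) whose
tokens draw the last concept with probability 0.9. The 20×20 grid with
prevalence 0.1 gives regions of ~20 tokens with genuine interiors; on
much smaller grids the regions degenerate to boundary-only blobs whose
r=1 neighborhoods are indistinguishable from adjacent background, which
tests the head's failure mode rather than its operating regime. Every
datum gets an independent child of a single `SeedSequence`, so datasets
are reproducible and order-independent.

Realism limits: embeddings are exchangeable given concepts (no spatial
autocorrelation of noise), concepts are well-separated and equidistant,
signal is a single concept rather than a motif, and class-0 data are
entirely signal-free. Real encoder embeddings violate all of these to
varying degrees; the generator validates the machinery, not the
difficulty of any real task.

## Numerical choices

- Neighborhoods come from boolean sparse powers of `A + I`, so
  `N_r` is exact hop distance, not weighted distance.
- k-means centroids are lexicographically sorted after fitting and
  assignment ties break to the lowest concept index, making concept IDs
  and everything downstream deterministic for a given seed.
- Bigram keys are canonical unordered pairs (`c1 ≤ c2`), giving the
  `K(K+1)/2` bigram budget; self-pairs within a neighborhood use the
  choose-2 correction `(h² − h)/2` so a vertex never pairs with itself.
- Welch test with both classes constant for a key (scipy returns NaN):
  resolved to p=0 if the constants differ, p=1 if equal.
- AUPRC is step-summed average precision
  (`sklearn.metrics.average_precision_score`); ratio metrics define
  0/0 = 0; degenerate masks (all-positive or all-negative) are skipped
  and counted rather than silently scored.
- All file artifacts are text with floats written as `%.17g` (exact
  round-trip), and pipeline reruns are byte-identical; this is enforced
  by tests.

## Limitations

- Attribution resolution is bounded by the quantizer: signal split
  across concepts, or merged with background into one concept, is
  invisible to the kernel.
- Fold-change weights are marginal per-key statistics; strongly
  correlated keys (e.g. `mono(c)` and `bi(c,c)`) carry redundant weight,
  which is why the score, not any single weight, is the unit of
  interpretation. The linear variant shares credit but inherits the
  usual elastic-net shrinkage biases.
- Significance filtering at fixed `α` is per-key; with many keys some
  null keys survive at roughly rate `α` (measured by the acceptance
  script), so individual small weights should not be over-read.
- Scores at graph boundaries have smaller neighborhoods and hence
  smaller magnitude ranges; the optional normalization trades this
  against losing the additive semantics.
- The head is not an encoder: garbage embeddings in, garbage concepts
  out. Model selection can only compare candidates within the quantizer
  family it is given.
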