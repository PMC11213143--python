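# prospector

Token-level feature attribution for weakly labelled, graph-structured data.

Many scientific datasets come as large collections of tokens with a single
label per *datum* — a pathology slide labelled malignant/benign, a protein
sequence labelled binder/non-binder — while the scientific question lives at
the token level: *which* tokens carry the class signal? `prospector`
implements a lightweight, encoder-agnostic attribution head that sits on top
of any frozen token embedder and produces a per-token score map ("prospect
map") from datum-level labels alone.

## Model

Each datum is a **map graph** `G(V, E)`: vertices are tokens, edges encode
spatial or sequential adjacency (sequences, grids, point clouds are built
in). Given token embeddings `x_v ∈ R^d`, the head has two layers:

**Layer I — quantization.** A k-means quantizer trained on a pooled sample
of embeddings maps every token to one of `K` discrete *concepts*,
`c_v = q(x_v) ∈ {0, …, K−1}`, turning each datum into a categorical **data
sprite** that keeps the graph topology.

**Layer II — K²conv.** For a hop radius `r`, each datum is rolled up into a
*sprite embedding* `z`: counts of concept **monograms** and unordered
**skip-bigrams** accumulated over every vertex's r-neighborhood `N_r(v)`
(hop distance ≤ r, including `v`). With `l1` rescaling these become
per-datum frequency vectors. A global **kernel** `w` assigns each key a
class-association weight, fitted either by

- `fold_change` (default): `w(k) = log2(z̄₁(k)+ε) − log2(z̄₀(k)+ε)`, kept
  only where a Welch two-sample t-test rejects equal class means at level
  `α` (significance filtering acts as regularization); or
- `linear`: coefficients of an elastic-net logistic regression predicting
  the datum label from `z`.

Token scores are a graph convolution of the kernel against the sprite:

```
score(v) = Σ_{u ∈ N_r(v)} w(c_u) + Σ_{{u,t} ⊆ N_r(v), u≠t} w({c_u, c_t})
```

so a token scores highly when its neighborhood is rich in class-1-associated
concepts and concept co-occurrences. The whole head uses at most
`K + K(K+1)/2` parameters, is fitted in seconds, and never needs token-level
supervision.

The package also provides evaluation metrics against ground-truth masks
(AUPRC, threshold-set average precision, precision / Dice / MCC at a
threshold, region prevalence and dispersion), lexicographic model selection
over a `(K, r, variant)` grid, and a synthetic multiple-instance generator
with planted signal regions for end-to-end validation.

## Worked example

```python
import prospector as pr

# 1. simulate a labelled dataset (defaults: 20x20 grids, K_true=5 concepts)
cfg = pr.SynthConfig(n_class0=20, n_class1=20, seed=0)
train = [d.graph for d in pr.generate_dataset(cfg)]

# 2. fit both layers: quantizer (Layer I) + fold-change kernel (Layer II)
fitted = pr.fit_prospector(train, K=5, r=1, seed=0)
print("stored kernel keys:", fitted.kernel.n_stored())
top = sorted(fitted.kernel.weights, key=fitted.kernel.weights.get, reverse=True)
for key in top[:3]:
    print(f"  {key}  weight={fitted.kernel.weights[key]:+.3f}")

# 3. score held-out data and evaluate against the planted regions
test_cfg = pr.SynthConfig(n_class0=0, n_class1=5, seed=1)
test = [d.graph for d in pr.generate_dataset(test_cfg)]
for res in pr.evaluate_maps(fitted.predict(test), test):
    print(f"  {res.datum_id}: AUPRC={res.auprc:.3f} dice={res.dice:.3f}")
```

Output:

```
stored kernel keys: 18
  bi(3,3)  weight=+15.414
  mono(3)  weight=+14.250
  bi(1,3)  weight=+14.002
  class1_0000: AUPRC=0.945 dice=0.645
  class1_0001: AUPRC=0.966 dice=0.690
  class1_0002: AUPRC=0.942 dice=0.667
  class1_0003: AUPRC=0.945 dice=0.702
  class1_0004: AUPRC=0.983 dice=0.630
```

The generator plants regions of a designated signal concept; after fitting,
the top-weighted kernel keys all involve the (relabelled) signal concept,
and the score maps localize the planted regions at AUPRC ≈ 0.95 against a
background prevalence of 0.1.

## Command line

The `prospector` CLI drives the same pipeline from a YAML config
(`data_dir`, `output_dir`, `seed`, plus `simulate:`, `quantizer:`,
`kernel:`, `grid:` and `eval:` sections):

```
prospector simulate -c config.yaml        # write a synthetic dataset (TSV)
prospector fit      -c config.yaml        # fit quantizer + kernel
prospector predict  -c config.yaml        # write per-token prospect maps
prospector evaluate -c config.yaml        # per-datum and summary metrics
prospector tune     -c config.yaml        # grid search over (K, r, variant)
```

All artifacts are deterministic text files: reruns with the same config and
seed are byte-identical.

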