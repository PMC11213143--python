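import numpy as np
import pytest

import prospector as pr
from prospector.errors import FitError, InvalidArgumentError
from prospector.kernel import load_kernel, save_kernel
from prospector.sprite import FeatureKey, n_canonical_keys


def make_embedding(values, label, datum_id="d", K=6, r=1):
    """Embedding with given rescaled monogram values (concept -> prob)."""
    counts = {FeatureKey.mono(c): v * 100 for c, v in values.items()}
    e = pr.SpriteEmbedding(counts=counts, K=K, r=r, datum_id=datum_id,
                           label=label)
    e.rescaled = {FeatureKey.mono(c): v for c, v in values.items()}
    return e


def welch_pvalue(x, y):
    """Hand-rolled Welch two-sample t-test (oracle for the filter)."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    tstat = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return 2 * tdist.sf(abs(tstat), df)


class TestClassProfiles:
    def test_identical_data_give_that_datum(self):
        e = [make_embedding({0: 0.5, 1: 0.5}, 0, "a"),
             make_embedding({0: 0.5, 1: 0.5}, 0, "b"),
             make_embedding({2: 1.0}, 1, "c")]
        prof = pr.compute_class_profiles(e)
        assert prof.mean_class0[FeatureKey.mono(0)] == pytest.approx(0.5)
        assert prof.n0 == 2 and prof.n1 == 1

    def test_missing_keys_average_as_zero(self):
        e = [make_embedding({0: 1.0}, 0, "a"),
             make_embedding({1: 1.0}, 0, "b"),
             make_embedding({2: 1.0}, 1, "c")]
        prof = pr.compute_class_profiles(e)
        assert prof.mean_class0[FeatureKey.mono(0)] == pytest.approx(0.5)
        assert prof.mean_class0[FeatureKey.mono(1)] == pytest.approx(0.5)

    def test_order_invariant(self, rng):
        embs = [make_embedding({0: p, 1: 1 - p}, int(i >= 5), str(i))
                for i, p in enumerate(rng.random(10))]
        p1 = pr.compute_class_profiles(embs)
        p2 = pr.compute_class_profiles(embs[::-1])
        for a, b in ((p1.mean_class0, p2.mean_class0),
                     (p1.mean_class1, p2.mean_class1)):
            assert set(a) == set(b)
            for key in a:
                assert a[key] == pytest.approx(b[key], rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pr.compute_class_profiles([make_embedding({0: 1.0}, 0)])


def _two_class_set(vals0, vals1):
    """Constant-within-class embeddings (degenerate Welch case: p=0 when
    the class constants differ)."""
    embs = []
    for i in range(3):
        embs.append(make_embedding(vals0, 0, f"n{i}"))
        embs.append(make_embedding(vals1, 1, f"p{i}"))
    return embs


class TestFoldChange:
    def test_hand_computed_log_ratios(self):
        # mean1 = 0.5 vs mean0 = 0.25 -> +1; 0.5 vs 0.75 -> log2(2/3)
        embs = _two_class_set({0: 0.25, 1: 0.75}, {0: 0.5, 1: 0.5})
        prof = pr.compute_class_profiles(embs)
        kern = pr.fit_kernel_foldchange(prof, embs, alpha=0.05, epsilon=1e-12)
        assert kern.lookup(FeatureKey.mono(0)) == pytest.approx(1.0, abs=1e-6)
        assert kern.lookup(FeatureKey.mono(1)) == pytest.approx(
            np.log2(0.5 / 0.75), abs=1e-6)

    def test_equal_means_give_zero_weights(self):
        embs = _two_class_set({0: 0.5, 1: 0.5}, {0: 0.5, 1: 0.5})
        prof = pr.compute_class_profiles(embs)
        kern = pr.fit_kernel_foldchange(prof, embs)
        assert kern.n_stored() == 0
        assert kern.lookup(FeatureKey.mono(0)) == 0.0

    def test_planted_key_survives_with_largest_positive_weight(self, rng):
        # key 3 at rate 0.5 in class1 vs 0.05 in class0, n=40/class
        embs = []
        for i in range(40):
            p = 0.05 + rng.normal(0, 0.01)
            embs.append(make_embedding({3: p, 0: 1 - p}, 0, f"n{i}"))
        for i in range(40):
            p = 0.5 + rng.normal(0, 0.01)
            embs.append(make_embedding({3: p, 0: 1 - p}, 1, f"p{i}"))
        prof = pr.compute_class_profiles(embs)
        kern = pr.fit_kernel_foldchange(prof, embs, alpha=0.05)
        k_star = FeatureKey.mono(3)
        assert k_star in kern.weights
        assert kern.weights[k_star] == max(kern.weights.values())
        assert kern.weights[k_star] > 0
        # significance filter agrees with an independent Welch implementation
        x1 = [e.rescaled[k_star] for e in embs if e.label == 1]
        x0 = [e.rescaled[k_star] for e in embs if e.label == 0]
        assert welch_pvalue(x1, x0) < 0.05
        assert kern.p_values[k_star] == pytest.approx(
            welch_pvalue(x1, x0), rel=1e-6)

    def test_antisymmetric_under_label_swap(self, rng):
        embs = []
        for i in range(20):
            p = np.clip(0.3 + rng.normal(0, 0.05), 0.01, 0.99)
            embs.append(make_embedding({0: p, 1: 1 - p}, 0, f"n{i}"))
            q = np.clip(0.6 + rng.normal(0, 0.05), 0.01, 0.99)
            embs.append(make_embedding({0: q, 1: 1 - q}, 1, f"p{i}"))
        kern = pr.fit_kernel_foldchange(pr.compute_class_profiles(embs), embs)
        flipped = [make_embedding(
            {k.c1: v for k, v in e.rescaled.items()}, 1 - e.label, e.datum_id)
            for e in embs]
        kern_f = pr.fit_kernel_foldchange(
            pr.compute_class_profiles(flipped), flipped)
        assert set(kern.weights) == set(kern_f.weights)
        for key, w in kern.weights.items():
            assert kern_f.weights[key] == pytest.approx(-w, rel=1e-9)

    def test_surviving_sets_nested_in_alpha(self, rng):
        embs = []
        for i in range(15):
            vals = rng.dirichlet([2, 2, 2, 2])
            embs.append(make_embedding(dict(enumerate(vals)), 0, f"n{i}", K=4))
            vals = rng.dirichlet([2, 2, 2.5, 3])
            embs.append(make_embedding(dict(enumerate(vals)), 1, f"p{i}", K=4))
        prof = pr.compute_class_profiles(embs)
        prev = set()
        for alpha in (0.001, 0.01, 0.05, 0.2, 0.5):
            kern = pr.fit_kernel_foldchange(prof, embs, alpha=alpha)
            assert prev <= set(kern.weights)
            prev = set(kern.weights)

    def test_within_class_order_invariant(self, rng):
        embs = []
        for i in range(10):
            p = rng.uniform(0.2, 0.8)
            embs.append(make_embedding({0: p, 1: 1 - p}, i % 2, str(i)))
        k1 = pr.fit_kernel_foldchange(pr.compute_class_profiles(embs), embs)
        shuffled = [embs[i] for i in rng.permutation(len(embs))]
        k2 = pr.fit_kernel_foldchange(
            pr.compute_class_profiles(shuffled), shuffled)
        assert k1.weights == k2.weights

    def test_invalid_alpha_rejected(self):
        embs = _two_class_set({0: 1.0}, {1: 1.0})
        prof = pr.compute_class_profiles(embs)
        with pytest.raises(InvalidArgumentError):
            pr.fit_kernel_foldchange(prof, embs, alpha=1.5)

    def test_parameter_budget(self):
        embs = _two_class_set({0: 0.2, 1: 0.8}, {2: 0.7, 3: 0.3})
        kern = pr.fit_kernel_foldchange(pr.compute_class_profiles(embs), embs)
        K = kern.K
        assert kern.n_stored() <= n_canonical_keys(K) <= 2 * K + K * K


class TestLinearVariant:
    def _separable(self, rng, n=40):
        embs = []
        for i in range(n):
            noise = rng.uniform(0.3, 0.7)
            embs.append(make_embedding({0: noise, 1: 1 - noise}, 0, f"n{i}"))
            noise = rng.uniform(0.2, 0.5)
            embs.append(make_embedding(
                {0: noise, 1: 0.8 - noise, 2: 0.2}, 1, f"p{i}"))
        return embs

    def test_separating_key_dominates(self, rng):
        embs = self._separable(rng)
        kern = pr.fit_kernel_linear(embs, lambda_mix=0.5, strength=0.01)
        key = FeatureKey.mono(2)  # present iff class 1
        assert kern.weights[key] > 0
        assert kern.weights[key] == max(
            kern.weights.values(), key=abs)

    def test_lasso_limit_is_sparse(self, rng):
        embs = self._separable(rng)
        kern = pr.fit_kernel_linear(embs, lambda_mix=1.0, strength=100.0)
        dense = pr.fit_kernel_linear(embs, lambda_mix=0.0, strength=0.01)
        assert kern.n_stored() < dense.n_stored()

    def test_label_flip_negates_dominant_signs(self, rng):
        embs = self._separable(rng)
        kern = pr.fit_kernel_linear(embs, lambda_mix=0.0, strength=1.0)
        flipped = [make_embedding(
            {k.c1: v for k, v in e.rescaled.items()}, 1 - e.label, e.datum_id)
            for e in embs]
        kern_f = pr.fit_kernel_linear(flipped, lambda_mix=0.0, strength=1.0)
        key = FeatureKey.mono(2)
        assert np.sign(kern.weights[key]) == -np.sign(kern_f.weights[key])

    def test_degenerate_design_raises(self):
        embs = [make_embedding({0: 1.0}, i % 2, str(i)) for i in range(6)]
        with pytest.raises(FitError):
            pr.fit_kernel_linear(embs)


class TestLookupAndSerialization:
    def _kernel(self):
        return pr.Kernel(
            weights={FeatureKey.mono(1): 0.5, FeatureKey.bi(2, 5): -1.25},
            K=6, r=2, variant="fold_change",
            hyperparams={"alpha": 0.05, "epsilon": 1e-6},
            p_values={FeatureKey.mono(1): 0.01, FeatureKey.bi(2, 5): 0.002})

    def test_absent_key_is_zero(self):
        assert self._kernel().lookup(FeatureKey.mono(0)) == 0.0

    def test_bigram_lookup_symmetric(self):
        k = self._kernel()
        assert pr.kernel_lookup(k, FeatureKey.bi(5, 2)) == -1.25
        assert pr.kernel_lookup(k, FeatureKey.bi(2, 5)) == -1.25

    def test_out_of_range_concept_rejected(self):
        with pytest.raises(InvalidArgumentError):
            self._kernel().lookup(FeatureKey.mono(6))

    def test_round_trip(self, tmp_path):
        k = self._kernel()
        save_kernel(k, tmp_path / "k.tsv")
        k2 = load_kernel(tmp_path / "k.tsv")
        assert k2.weights == k.weights
        assert k2.p_values == k.p_values
        assert (k2.K, k2.r, k2.variant) == (6, 2, "fold_change")


class TestBenjaminiHochberg:
    def test_matches_scipy_adjusted_pvalues(self):
        from scipy.stats import false_discovery_control

        from prospector.kernel import _benjamini_hochberg

        rng = np.random.default_rng(42)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            for alpha in (0.01, 0.05, 0.2):
                expected = false_discovery_control(p, method="bh") <= alpha
                assert np.array_equal(
                    _benjamini_hochberg(p, alpha), expected)

    def test_hand_example(self):
        from prospector.kernel import _benjamini_hochberg

        # step-up on sorted p=(0.01, 0.02, 0.04, 0.8) with alpha=0.05:
        # thresholds are (0.0125, 0.025, 0.0375, 0.05), so the largest k
        # with p_(k) <= alpha*k/m is k=2 and exactly two are rejected
        p = np.array([0.8, 0.01, 0.04, 0.02])
        assert _benjamini_hochberg(p, 0.05).tolist() == [False, True, False,
                                                         True]
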