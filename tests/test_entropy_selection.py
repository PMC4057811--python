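import numpy as np
import pytest

from mfgi.entropy_selection import (
    SelectionConfig,
    binary_entropy,
    compute_all_ratios,
    conditional_entropy,
    information_gain_ratio,
    permutation_select,
    pooled_permutation_select,
)
from mfgi.genotype_models import (
    PairClass,
    classify_pairs,
    code_incompatibility,
    get_model,
    standard_models,
)


def brute_force_ratios(y, cls):
    """Independent recount of every model's 2x2 table by explicit loops."""
    y = list(map(int, y))
    h_d = binary_entropy(sum(y) / len(y))
    out = []
    for model in standard_models():
        risk = [1 if PairClass(c) in model.risk_classes else 0 for c in cls]
        groups = {}
        for yi, ri in zip(y, risk):
            groups.setdefault(ri, []).append(yi)
        h_cond = sum(
            (len(g) / len(y)) * binary_entropy(sum(g) / len(g))
            for g in groups.values()
        )
        out.append(0.0 if h_d == 0 else 1.0 - h_cond / h_d)
    return np.array(out)


class TestEntropies:
    def test_binary_entropy_values(self):
        assert binary_entropy(0.5) == pytest.approx(1.0)
        assert binary_entropy(0.0) == 0.0
        assert binary_entropy(1.0) == 0.0
        assert binary_entropy(0.25) == pytest.approx(0.8112781244591328, abs=1e-12)

    def test_binary_entropy_symmetric(self, rng):
        for p in rng.random(20):
            assert binary_entropy(p) == pytest.approx(binary_entropy(1 - p), abs=1e-12)

    def test_binary_entropy_rejects_outside_unit_interval(self):
        with pytest.raises(ValueError):
            binary_entropy(1.2)

    def test_conditional_entropy_constant_risk(self, rng):
        y = rng.integers(0, 2, 30)
        risk = np.ones(30, dtype=int)
        assert conditional_entropy(y, risk) == pytest.approx(binary_entropy(y.mean()))

    def test_conditional_entropy_perfect_predictor(self, rng):
        y = rng.integers(0, 2, 30)
        assert conditional_entropy(y, y) == 0.0

    def test_conditional_entropy_frozen_example(self):
        # 2x2 table counted by hand: risk=1 group (1,0); risk=0 group (1,0,0,0)
        y = np.array([1, 1, 0, 0, 0, 0])
        risk = np.array([1, 0, 1, 0, 0, 0])
        expected = (2 / 6) * 1.0 + (4 / 6) * binary_entropy(1 / 4)
        assert conditional_entropy(y, risk) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.8741854163060885, abs=1e-12)

    def test_conditional_entropy_length_mismatch(self):
        with pytest.raises(ValueError):
            conditional_entropy(np.ones(3), np.ones(4))

    def test_information_gain_ratio_extremes(self, rng):
        y = rng.integers(0, 2, 50)
        while y.min() == y.max():
            y = rng.integers(0, 2, 50)
        assert information_gain_ratio(y, y) == pytest.approx(1.0)
        assert information_gain_ratio(y, np.zeros(50, int)) == pytest.approx(0.0)

    def test_information_gain_ratio_frozen_example(self):
        y = np.array([1, 1, 0, 0, 0, 0])
        risk = np.array([1, 0, 1, 0, 0, 0])
        expected = 1.0 - conditional_entropy(y, risk) / binary_entropy(1 / 3)
        assert information_gain_ratio(y, risk) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.048035084242561976, abs=1e-12)

    def test_degenerate_phenotype_gives_zero(self):
        assert information_gain_ratio(np.ones(10), np.arange(10) % 2) == 0.0

    def test_conditioning_never_increases_entropy(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            y = rng.integers(0, 2, n)
            risk = rng.integers(0, 2, n)
            assert conditional_entropy(y, risk) <= binary_entropy(y.mean()) + 1e-12


class TestComputeAllRatios:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 50))
            cls = rng.choice(5, size=n).astype(np.int8)
            y = rng.integers(0, 2, n)
            fast = compute_all_ratios(y, cls)
            slow = brute_force_ratios(y, cls)
            np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_all_compatible_gives_eleven_zeros(self, rng):
        cls = np.zeros(30, dtype=np.int8)
        y = rng.integers(0, 2, 30)
        assert compute_all_ratios(y, cls).tolist() == [0.0] * 11

    def test_m1_indicator_phenotype(self):
        """y equal to the M1 indicator makes Model 1 a perfect predictor."""
        cls = np.array([PairClass.M1] * 5 + [PairClass.COMPATIBLE] * 10
                       + [PairClass.M2] * 3, dtype=np.int8)
        y = (cls == PairClass.M1).astype(int)
        ratios = compute_all_ratios(y, cls)
        assert ratios[0] == pytest.approx(1.0)
        for mid in (5, 6, 7, 11):  # every model containing M1 carries signal
            assert ratios[mid - 1] > 0
        assert ratios[3 - 1] == pytest.approx(0.0, abs=1e-12) or ratios[3 - 1] < ratios[0]

    def test_relabel_invariance(self, small_dataset):
        y, cls = small_dataset
        np.testing.assert_allclose(compute_all_ratios(y, cls),
                                   compute_all_ratios(1 - y, cls), atol=1e-12)


class TestPermutationSelect:
    def test_count_resampling_matches_label_shuffle(self, rng):
        """The hypergeometric count engine reproduces explicit label shuffles.

        Both nulls are Monte-Carlo samples of the same distribution of
        R_b^max; their first two moments and upper quantiles must agree.
        """
        from mfgi.entropy_selection import _permuted_max_ratios
        from mfgi.genotype_models import class_counts

        n = 300
        cls = rng.choice(5, size=n, p=[0.6, 0.05, 0.05, 0.15, 0.15]).astype(np.int8)
        y = (rng.random(n) < 0.2).astype(int)
        n_k, c_k = class_counts(cls, y)

        b = 6000
        engine = _permuted_max_ratios(n_k, int(c_k.sum()), b, rng)
        shuffled = np.empty(b)
        y_perm = y.copy()
        for i in range(b):
            rng.shuffle(y_perm)
            shuffled[i] = compute_all_ratios(y_perm, cls).max()
        assert engine.mean() == pytest.approx(shuffled.mean(), rel=0.05)
        assert np.quantile(engine, 0.95) == pytest.approx(
            np.quantile(shuffled, 0.95), rel=0.10)

    def test_constant_phenotype_defaults(self):
        cls = np.array([PairClass.M1, PairClass.COMPATIBLE] * 10, dtype=np.int8)
        res = permutation_select(np.ones(20, int), cls,
                                 SelectionConfig(n_permutations=100, tau=0.05, seed=0))
        assert res.defaulted and res.final_model_id == 11 and res.p_empirical is None

    def test_no_mismatch_defaults(self, rng):
        cls = np.zeros(20, dtype=np.int8)
        res = permutation_select(rng.integers(0, 2, 20), cls,
                                 SelectionConfig(n_permutations=100, tau=0.05, seed=0))
        assert res.defaulted and res.final_model_id == 11

    def test_perfect_signal_selects_model_one(self):
        """R^max = 1 cannot be strictly exceeded, so p = 0 and Model 1 wins."""
        cls = np.array([PairClass.M1] * 6 + [PairClass.COMPATIBLE] * 14, dtype=np.int8)
        y = (cls == PairClass.M1).astype(int)
        res = permutation_select(y, cls,
                                 SelectionConfig(n_permutations=200, tau=0.01, seed=1))
        assert res.r_max == pytest.approx(1.0)
        assert res.p_empirical == 0.0
        assert res.final_model_id == 1 and not res.defaulted

    def test_tau_below_permutation_resolution_rejected(self):
        with pytest.raises(ValueError):
            SelectionConfig(n_permutations=100, tau=0.001)

    def test_reproducible_with_seed(self, small_dataset):
        y, cls = small_dataset
        cfg = SelectionConfig(n_permutations=500, tau=0.05, seed=99)
        a = permutation_select(y, cls, cfg)
        b = permutation_select(y, cls, cfg)
        assert np.array_equal(a.ratios, b.ratios)
        assert (a.candidate_id, a.r_max, a.p_empirical, a.final_model_id,
                a.defaulted) == (b.candidate_id, b.r_max, b.p_empirical,
                                 b.final_model_id, b.defaulted)

    def test_pvalue_approximately_uniform_under_null(self, rng):
        """Under exchangeability P(p_empirical < t) is close to t."""
        n, t, m = 200, 0.2, 300
        cfg_seed = np.random.default_rng(7)
        hits = 0
        for _ in range(m):
            cls = rng.choice(5, size=n, p=[0.6, 0.05, 0.05, 0.15, 0.15]).astype(np.int8)
            y = (rng.random(n) < 0.15).astype(int)
            if y.sum() in (0, n):
                continue
            res = permutation_select(y, cls, SelectionConfig(
                n_permutations=400, tau=0.05, seed=cfg_seed))
            hits += res.p_empirical < t
        # 99.7% binomial band around t
        band = 3 * np.sqrt(t * (1 - t) / m)
        assert abs(hits / m - t) < band + 0.02

    def test_add_one_correction_shifts_p(self, small_dataset):
        y, cls = small_dataset
        base = permutation_select(y, cls, SelectionConfig(500, 0.05, seed=3))
        corr = permutation_select(y, cls, SelectionConfig(500, 0.05, seed=3,
                                                          add_one_correction=True))
        if base.p_empirical is not None:
            assert corr.p_empirical == pytest.approx(
                (1 + base.p_empirical * 500) / 501)


class TestPooledSelection:
    def test_pool_size_is_loci_times_permutations(self, rng):
        y = np.zeros(721, dtype=int)
        y[:136] = 1
        rng.shuffle(y)
        loci = [rng.choice(5, size=721, p=[0.68, 0.03, 0.03, 0.13, 0.13]).astype(np.int8)
                for _ in range(742)]
        results, pool = pooled_permutation_select(y, loci, 20, 0.05, seed=2)
        assert pool.size == 742 * 20 == 14840
        assert len(results) == 742

    def test_identical_loci_get_identical_pvalues(self, rng):
        y = rng.integers(0, 2, 100)
        cls = rng.choice(5, size=100).astype(np.int8)
        results, _ = pooled_permutation_select(y, [cls, cls.copy()], 50, 0.05, seed=4)
        assert results[0].r_max == results[1].r_max
        assert results[0].p_empirical == results[1].p_empirical

    def test_single_locus_agrees_with_per_locus_engine(self, rng):
        """With L = 1 the pooled null is a per-locus null of the same size."""
        y = rng.integers(0, 2, 150)
        cls = rng.choice(5, size=150).astype(np.int8)
        (pooled_res,), pool = pooled_permutation_select(y, [cls], 2000, 0.05, seed=5)
        per_locus = permutation_select(y, cls, SelectionConfig(2000, 0.05, seed=5))
        assert pooled_res.candidate_id == per_locus.candidate_id
        assert pooled_res.r_max == per_locus.r_max
        if per_locus.p_empirical is not None:
            assert pooled_res.p_empirical == pytest.approx(per_locus.p_empirical,
                                                           abs=0.03)

    def test_degenerate_locus_defaults_and_contributes_nothing(self, rng):
        y = rng.integers(0, 2, 60)
        live = rng.choice(5, size=60).astype(np.int8)
        dead = np.zeros(60, dtype=np.int8)  # no mismatched pairs at all
        results, pool = pooled_permutation_select(y, [live, dead], 30, 0.05, seed=6)
        assert pool.size == 30
        assert results[1].defaulted and results[1].final_model_id == 11

    def test_per_locus_exclusions_respected(self, rng):
        """Families flagged Mendel-error at one locus drop out of it only."""
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 1, 0] * 6)
        cls = rng.choice(5, size=60).astype(np.int8)
        cls_with_errors = cls.copy()
        cls_with_errors[:5] = PairClass.MENDEL_ERROR
        (res,), _ = pooled_permutation_select(y, [cls_with_errors], 50, 0.05, seed=7)
        expected = compute_all_ratios(y[5:], cls_with_errors[5:])
        np.testing.assert_allclose(res.ratios, expected, atol=1e-12)
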