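import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efbdba import (
    BDBAConfig,
    ValidationError,
    build_pool,
    class_relevance,
    complementarity,
    fisher_score,
    improved_fcbf,
    pearson,
    smote_balance,
)
from efbdba.ensemble_filter import RELEVANCE_WEIGHT


class TestPearson:
    def test_self_correlation(self, rng):
        x = rng.normal(size=10)
        assert pearson(x, x) == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        x = rng.normal(size=10)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_closed_form(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 8))
            expected = np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std())
            assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_zero(self):
        assert pearson(np.ones(5), np.arange(5.0)) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            pearson(np.ones(3), np.ones(4))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=12),
        st.integers(0, 2**31 - 1),
    )
    def test_bounded_in_unit_interval(self, xs, seed):
        x = np.array(xs)
        y = np.random.default_rng(seed).normal(size=len(x))
        r = pearson(x, y)
        assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12


class TestSmote:
    def test_balanced_is_noop(self, rng):
        pos = np.arange(6.0).reshape(3, 2)
        neg = pos + 1
        p, n = smote_balance(pos, neg, k=2, rng=rng)
        np.testing.assert_array_equal(p, pos)
        np.testing.assert_array_equal(n, neg)

    def test_rand_zero_duplicates_seed_sample(self, scripted):
        pos = np.array([[0.0, 0.0], [2.0, -2.0]])
        neg = np.zeros((3, 2))
        # draws: seed index i=0, neighbour pick 0, interpolation rand 0.0
        fake = scripted(randoms=[0.0], integers=[0, 0])
        p, _ = smote_balance(pos, neg, k=5, rng=fake)
        np.testing.assert_array_equal(p[2], pos[0])

    def test_absolute_difference_interpolation(self, scripted):
        # s_i=(0,0), s_j=(2,-2), rand=0.5 -> (1,1): |.| makes both gaps +2
        pos = np.array([[0.0, 0.0], [2.0, -2.0]])
        neg = np.zeros((3, 2))
        fake = scripted(randoms=[0.5], integers=[0, 0])
        p, _ = smote_balance(pos, neg, k=5, rng=fake)
        np.testing.assert_allclose(p[2], [1.0, 1.0])

    def test_output_sizes_equal(self, rng):
        pos = rng.normal(size=(4, 3))
        neg = rng.normal(size=(9, 3))
        p, n = smote_balance(pos, neg, k=3, rng=rng)
        assert len(p) == len(n) == 9


class TestClassRelevance:
    def test_identical_class_profiles_give_zero(self, rng):
        f = np.concatenate([np.arange(6.0), np.arange(6.0)])
        labels = np.array([1] * 6 + [0] * 6)
        assert class_relevance(f, labels, rng=rng) == pytest.approx(0.0)

    def test_upper_bound_is_point_eight(self, rng):
        # r_cf = 0.8 * (1 - r_pn) cannot exceed the 0.8 guard
        for _ in range(10):
            f = rng.normal(size=20)
            labels = (rng.random(20) < 0.5).astype(int)
            labels[:2] = [0, 1]
            r = class_relevance(f, labels, rng=rng)
            assert 0.0 <= r <= RELEVANCE_WEIGHT

    def test_balanced_case_matches_sorted_pearson_oracle(self, rng):
        f = rng.normal(size=12)
        labels = np.array([1, 0] * 6)
        # balanced: no oversampling; oracle straight from the definition
        fp = np.sort(f[labels == 1])
        fn = np.sort(f[labels == 0])
        expected = 0.8 * (1.0 - abs(np.corrcoef(fp, fn)[0, 1]))
        assert class_relevance(f, labels, rng=rng) == pytest.approx(expected, abs=1e-12)


class TestComplementarity:
    def test_identical_samples_zero(self, dataset_factory, rng):
        vals = np.tile([1.0, 2.0], (6, 1))
        ds = dataset_factory(vals, [0, 1] * 3)
        assert complementarity(0, 1, ds, n=6, rng=rng) == 0.0

    def test_two_sample_exhaustive(self, dataset_factory, rng):
        # fp: (0,1), fq: (0,2) -> dis = 1 + 2 = 3 whichever sample is drawn
        ds = dataset_factory(np.array([[0.0, 0.0], [1.0, 2.0]]), [0, 1])
        assert complementarity(0, 1, ds, n=2, rng=rng) == pytest.approx(3.0)

    def test_symmetric_in_feature_order(self, dataset_factory):
        rng_vals = np.random.default_rng(3)
        ds = dataset_factory(rng_vals.normal(size=(10, 4)), [0, 1] * 5)
        c1 = complementarity(1, 3, ds, n=10, rng=np.random.default_rng(5))
        c2 = complementarity(3, 1, ds, n=10, rng=np.random.default_rng(5))
        assert c1 == pytest.approx(c2)

    def test_draw_count_clipped(self, dataset_factory, rng):
        ds = dataset_factory(np.arange(8.0).reshape(4, 2), [0, 1, 0, 1])
        c = complementarity(0, 1, ds, n=100, rng=rng)
        assert np.isfinite(c)


class TestImprovedFcbf:
    def test_single_candidate(self, dataset_factory, rng):
        ds = dataset_factory(np.random.default_rng(1).normal(size=(10, 3)), [0, 1] * 5)
        relevance = np.array([0.5, 0.1, 0.1])
        O, C = improved_fcbf(ds, delta=0.3, rng=rng, relevance=relevance)
        assert O == [0]
        assert C == []

    def test_perfectly_correlated_pair(self, dataset_factory, rng):
        base = np.random.default_rng(2).normal(size=10)
        vals = np.column_stack([base, base, np.random.default_rng(3).normal(size=10)])
        ds = dataset_factory(vals, [0, 1] * 5)
        relevance = np.array([0.5, 0.4, 0.0])
        O, C = improved_fcbf(ds, delta=0.3, rng=rng, relevance=relevance)
        assert O == [0]  # higher relevance wins
        assert C == [1]  # the eliminated copy is the only complementarity candidate

    def test_selection_bounded_by_candidates(self, dataset_factory, rng):
        ds = dataset_factory(np.random.default_rng(4).normal(size=(12, 8)), [0, 1] * 6)
        relevance = np.linspace(0.1, 0.7, 8)
        O, C = improved_fcbf(ds, delta=0.25, rng=rng, relevance=relevance)
        n_candidates = int((relevance > 0.25).sum())
        assert len(set(O) | set(C)) <= n_candidates

    def test_no_markov_blanket_violation_inside_O(self, dataset_factory, rng):
        ds = dataset_factory(np.random.default_rng(9).normal(size=(20, 10)), [0, 1] * 10)
        relevance = np.random.default_rng(10).uniform(0.2, 0.7, size=10)
        O, _ = improved_fcbf(ds, delta=0.1, rng=rng, relevance=relevance)
        for a_pos, a in enumerate(O):
            for b in O[a_pos + 1:]:
                r = abs(pearson(ds.values[:, a], ds.values[:, b]))
                assert r < min(relevance[a], relevance[b])

    def test_empty_candidates(self, dataset_factory, rng):
        ds = dataset_factory(np.random.default_rng(5).normal(size=(8, 3)), [0, 1] * 4)
        O, C = improved_fcbf(ds, delta=0.79, rng=rng, relevance=np.zeros(3))
        assert O == [] and C == []


def brute_force_fisher(values, labels):
    """Loop-based between/within class variance ratio."""
    n, p = values.shape
    out = np.empty(p)
    for j in range(p):
        col = values[:, j]
        m = col.mean()
        sb = 0.0
        sw = 0.0
        for c in np.unique(labels):
            grp = col[labels == c]
            sb += (len(grp) / n) * (grp.mean() - m) ** 2
            sw += sum((v - grp.mean()) ** 2 for v in grp) / n
        out[j] = sb / (sw + 1e-12)
    return out


class TestFisherScore:
    def test_constant_feature_zero(self, dataset_factory):
        ds = dataset_factory(np.full((6, 1), 2.0), [0] * 3 + [1] * 3)
        assert fisher_score(ds)[0] == pytest.approx(0.0)

    def test_perfectly_separated_feature(self, dataset_factory):
        ds = dataset_factory(np.array([[0.0], [0.0], [1.0], [1.0]]), [0, 0, 1, 1])
        j = fisher_score(ds)[0]
        # S_B = 0.25, S_w = 0 -> regularised to 0.25 / 1e-12
        assert j == pytest.approx(0.25 / 1e-12, rel=1e-6)

    def test_matches_brute_force(self, dataset_factory, rng):
        vals = rng.normal(size=(20, 5))
        labels = np.array([0, 1] * 10)
        ds = dataset_factory(vals, labels)
        np.testing.assert_allclose(
            fisher_score(ds), brute_force_fisher(vals, labels), atol=1e-10
        )

    def test_shift_invariant_scale_invariant(self, dataset_factory, rng):
        vals = rng.normal(size=(16, 3))
        labels = np.array([0, 1] * 8)
        base = fisher_score(dataset_factory(vals, labels))
        shifted = fisher_score(dataset_factory(vals + 100.0, labels))
        scaled = fisher_score(dataset_factory(vals * 3.0, labels))
        np.testing.assert_allclose(shifted, base, rtol=1e-6)
        np.testing.assert_allclose(scaled, base, rtol=1e-6)


class TestBuildPool:
    def test_pool_is_intersection_when_nonempty(self, dataset_factory, rng):
        gen = np.random.default_rng(12)
        vals = gen.normal(size=(30, 12))
        ds = dataset_factory(vals, [0, 1] * 15)
        cfg = BDBAConfig(fisher_top_k=12, relevance_keep_fraction=1.0,
                         relevance_threshold=0.0)
        fr = build_pool(ds, cfg)
        assert set(fr.pool) <= set(fr.fcbf_selected)
        if not fr.used_fallback:
            assert set(fr.pool) <= set(fr.fisher_topk)

    def test_disjoint_sets_fall_back_to_union(self, dataset_factory, rng, caplog):
        gen = np.random.default_rng(13)
        vals = gen.normal(size=(20, 10))
        ds = dataset_factory(vals, [0, 1] * 10)
        cfg = BDBAConfig(fisher_top_k=1)  # tiny Fisher set makes overlap unlikely
        fr = build_pool(ds, cfg)
        if fr.used_fallback:
            assert set(fr.pool) == set(fr.fcbf_selected) | set(fr.fisher_topk)
        assert len(fr.pool) >= 1

    def test_pool_size_capped_by_fisher_k_unless_fallback(self):
        from efbdba import make_synthetic, preprocess_pipeline

        ds, _ = make_synthetic(
            n_samples=60, n_features=300, n_informative=10, n_redundant=4,
            n_complementary_pairs=2, effect_size=2.0, rng=0,
        )
        clean, _ = preprocess_pipeline(ds)
        cfg = BDBAConfig(rng_seed=0, fisher_top_k=40)
        fr = build_pool(clean, cfg)
        if not fr.used_fallback:
            assert len(fr.pool) <= cfg.fisher_top_k
        else:
            assert set(fr.pool) == set(fr.fcbf_selected) | set(fr.fisher_topk)
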