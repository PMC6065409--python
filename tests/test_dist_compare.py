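"""Distribution-comparison statistics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetrobust.dist_compare import (
    AFHistogram,
    ComparisonConfig,
    cohort_pairwise_summary,
    emd,
    histogram_af,
    kde_abs_diff,
    ks_compare,
    l2_permutation_test,
    shared_af_correlation,
)
from hetrobust.io_core import VariantCall

from oracles import transport_cost


def _hist(abundances, bin_width=None):
    abundances = np.asarray(abundances, dtype=float)
    if bin_width is None:
        bin_width = 1.0 / len(abundances)
    return AFHistogram(bin_width=bin_width, abundances=abundances)


class TestHistogram:
    def test_half_open_bins_put_boundary_value_right(self):
        h = histogram_af([0.5, 0.5], bin_width=0.5)
        assert h.abundances.tolist() == [0.0, 1.0]

    def test_single_value_one_bin(self):
        h = histogram_af([0.3])
        assert h.abundances.sum() == 1.0
        assert np.count_nonzero(h.abundances) == 1

    def test_uniform_grid_at_bin_centers(self):
        centers = (np.arange(40) + 0.5) * 0.025
        h = histogram_af(centers, bin_width=0.025)
        assert np.allclose(h.abundances, 1 / 40)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            histogram_af([])


class TestEmd:
    def test_hand_cases(self):
        assert emd(_hist([1, 0, 0]), _hist([0, 0, 1])) == pytest.approx(2.0)
        assert emd(_hist([0.2, 0.3, 0.5]), _hist([0.2, 0.3, 0.5])) == 0.0
        # crossing-CDF case: the correct transport cost is 1.0, not the
        # abs-inside-the-inner-sum reading's 2.0
        assert emd(_hist([0.5, 0, 0.5]), _hist([0, 1, 0])) == pytest.approx(1.0)

    def test_mismatched_binning_rejected(self):
        with pytest.raises(ValueError):
            emd(_hist([1, 0]), _hist([1, 0, 0]))

    def test_matches_lp_transport_on_random_pairs(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 13))
            f1 = rng.dirichlet(np.ones(n))
            f2 = rng.dirichlet(np.ones(n))
            assert emd(_hist(f1), _hist(f2)) == pytest.approx(
                transport_cost(f1, f2), abs=1e-9
            )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_triangle_inequality(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 10))
        a, b, c = (_hist(r.dirichlet(np.ones(n))) for _ in range(3))
        assert emd(a, b) == pytest.approx(emd(b, a), abs=1e-12)
        assert emd(a, c) <= emd(a, b) + emd(b, c) + 1e-9


class TestKs:
    def test_identical_and_disjoint(self, rng):
        x = rng.uniform(0.1, 0.2, size=20)
        d_same, _ = ks_compare(x, x)
        assert d_same == 0.0
        d_disj, p = ks_compare(x, rng.uniform(0.4, 0.5, size=20))
        assert d_disj == 1.0 and p < 1e-6

    def test_statistic_matches_ecdf_sweep(self):
        x = np.array([0.1, 0.2, 0.3])
        y = np.array([0.1, 0.2, 0.3, 0.4])
        d, _ = ks_compare(x, y)
        grid = np.union1d(x, y)
        gaps = [
            abs(np.mean(x <= g) - np.mean(y <= g)) for g in grid
        ]
        assert d == pytest.approx(max(gaps))

    def test_small_inputs_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([0.1], [0.2, 0.3])

    def test_null_type_i_error_near_alpha(self, rng):
        # 500 same-distribution pairs at n=50: rejection rate ~ alpha
        rejections = 0
        for _ in range(500):
            _, p = ks_compare(rng.uniform(size=50), rng.uniform(size=50))
            rejections += p < 0.05
        assert 8 <= rejections <= 45  # binomial 99.9% band around 25


class TestKdeAbsDiff:
    def test_identical_is_zero(self, rng):
        x = rng.uniform(0.2, 0.6, size=50)
        assert kde_abs_diff(x, x) == 0.0

    def test_separated_clusters_approach_two(self, rng):
        a = rng.normal(0.25, 0.005, size=200).clip(0.1, 0.4)
        b = rng.normal(0.75, 0.005, size=200).clip(0.6, 0.9)
        assert kde_abs_diff(a, b) == pytest.approx(2.0, abs=0.02)

    def test_symmetric_and_nonnegative(self, rng):
        a, b = rng.uniform(size=30), rng.uniform(size=30)
        assert kde_abs_diff(a, b) == pytest.approx(kde_abs_diff(b, a))
        assert kde_abs_diff(a, b) >= 0

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            kde_abs_diff([0.1], [0.2], sigma=0.0)


class TestL2Permutation:
    def test_identical_inputs_give_zero_stat_p_one(self, rng):
        x = rng.uniform(0.2, 0.6, size=30)
        stat, p = l2_permutation_test(x, x, seed=1)
        assert stat == 0.0 and p == 1.0

    def test_separated_clusters_significant_across_seeds(self, rng):
        a = rng.normal(0.2, 0.02, size=50).clip(0.05, 0.35)
        b = rng.normal(0.6, 0.02, size=50).clip(0.45, 0.75)
        for seed in range(20):
            _, p = l2_permutation_test(a, b, seed=seed)
            assert p <= 0.05

    def test_deterministic_under_seed_and_p_bounds(self, rng):
        a, b = rng.uniform(size=25), rng.uniform(size=25)
        r1 = l2_permutation_test(a, b, seed=7)
        r2 = l2_permutation_test(a, b, seed=7)
        assert r1 == r2
        assert 0.0 < r1[1] <= 1.0  # ties-as-extreme keeps p positive


class TestCohortSummary:
    def test_bonferroni_fraction_hand_count(self, rng, monkeypatch):
        # three shared samples; plant ks_p values {0.001, 0.5, 0.9}
        import hetrobust.dist_compare as dc

        samples = {
            "c1": {f"s{i}": rng.uniform(size=30) for i in range(3)},
            "c2": {f"s{i}": rng.uniform(size=30) for i in range(3)},
        }
        planted = iter([0.001, 0.5, 0.9])

        real = dc.compare_af_samples

        def fake(afs1, afs2, sample_id="", caller_pair=("a", "b"), config=None):
            res = real(afs1, afs2, sample_id, caller_pair, config or ComparisonConfig())
            res.ks_p = next(planted)
            return res

        monkeypatch.setattr(dc, "compare_af_samples", fake)
        out = dc.cohort_pairwise_summary(samples, ComparisonConfig(n_permutations=5))
        summ = out[("c1", "c2")]
        assert summ["bonferroni_threshold"] == pytest.approx(0.05 / 3)
        assert summ["fraction_significant"] == pytest.approx(1 / 3)

    def test_identical_distributions_give_zero_fraction_and_emd(self, rng):
        afs = {f"s{i}": rng.uniform(size=40) for i in range(3)}
        out = cohort_pairwise_summary(
            {"c1": afs, "c2": afs}, ComparisonConfig(n_permutations=5)
        )
        summ = out[("c1", "c2")]
        assert summ["fraction_significant"] == 0.0
        assert summ["median_emd"] == 0.0

    def test_no_shared_samples_is_an_error(self, rng):
        with pytest.raises(ValueError, match="shared"):
            cohort_pairwise_summary(
                {"c1": {"a": rng.uniform(size=10)}, "c2": {"b": rng.uniform(size=10)}}
            )


def _calls(af_by_locus, caller="mutect"):
    return [
        VariantCall("1", pos, "A", "G", af, 0.0, 100, 100, "PASS", caller)
        for pos, af in af_by_locus.items()
    ]


class TestSharedAfCorrelation:
    def test_identical_sets_correlate_perfectly(self):
        calls = _calls({100: 0.2, 200: 0.3, 300: 0.5})
        assert shared_af_correlation(calls, calls) == pytest.approx(1.0)

    def test_anti_ordered_afs_give_minus_one(self):
        afs = {100: 0.1, 200: 0.2, 300: 0.3, 400: 0.4, 500: 0.5}
        rev = dict(zip(afs, [0.5, 0.4, 0.3, 0.2, 0.1]))
        assert shared_af_correlation(_calls(afs), _calls(rev)) == pytest.approx(-1.0)

    def test_jittered_duplicates_stay_above_0_95(self, rng):
        afs = {i: float(a) for i, a in enumerate(rng.uniform(0.1, 0.6, size=100), start=1)}
        jit = {i: float(np.clip(a + rng.normal(0, 0.01), 0.01, 0.99)) for i, a in afs.items()}
        assert shared_af_correlation(_calls(afs), _calls(jit)) > 0.95

    def test_too_few_shared_loci_is_missing(self):
        a = _calls({100: 0.2, 200: 0.3})
        b = _calls({100: 0.2, 200: 0.3})
        assert shared_af_correlation(a, b) is None
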