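"""MATH, AF/CNV dispersion scores, and the CNV-based SNV filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetrobust.heterogeneity import (
    af_std,
    cnv_std_at_snvs,
    extra_statistics,
    filter_snvs_by_cnv,
    math_score,
    wg_cnv_std,
)
from hetrobust.io_core import AFSample, CNVProfile, CNVSegment

from oracles import per_base_cnv_std


class TestMathScore:
    def test_hand_computed_value(self):
        # median 0.3, MAD 0.1 -> 100 * 1.4826 * 0.1 / 0.3
        assert math_score([0.1, 0.2, 0.3, 0.4, 0.5]) == pytest.approx(49.42)

    def test_constant_vector_scores_zero(self):
        assert math_score([0.4] * 7) == 0.0

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError, match="median"):
            math_score([0.0, 0.0, 0.0])

    @given(
        st.floats(0.05, 1.0),
        st.lists(st.floats(0.05, 0.99), min_size=3, max_size=50),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_purity_argument(self, c, afs):
        # purity rescales all AFs by one constant; MATH must not move
        base = math_score(afs)
        assert math_score(np.array(afs) * c) == pytest.approx(base, rel=1e-9)

    def test_accepts_ccf_scale_vectors(self):
        # CCFs live on [0, 1] like AFs but are typically larger; the
        # scorer is agnostic to which it gets
        ccfs = [0.2, 0.4, 0.6, 0.8, 1.0]
        assert math_score(ccfs) == pytest.approx(
            100 * 1.4826 * 0.2 / 0.6
        )


class TestAfStd:
    def test_simple_values(self):
        assert af_std([0.0, 1.0]) == 0.5
        assert af_std([0.3, 0.3, 0.3]) == 0.0
        assert af_std([0.3]) is None

    def test_matches_direct_formula(self, rng):
        x = rng.uniform(size=100)
        assert af_std(x) == pytest.approx(
            np.sqrt(np.mean((x - x.mean()) ** 2))
        )


def _profile(*triples):
    """triples of (start, end, mean) on chromosome 1."""
    return CNVProfile(
        sample_id="S",
        segments=[CNVSegment("1", a, b, m) for a, b, m in triples],
    )


class TestCnvStdAtSnvs:
    def test_two_level_lookup(self):
        prof = _profile((1, 100, 0.0), (101, 200, 1.0))
        assert cnv_std_at_snvs(prof, [("1", 50), ("1", 150)]) == 0.5

    def test_single_segment_is_zero(self):
        prof = _profile((1, 1000, 0.3))
        assert cnv_std_at_snvs(prof, [("1", 10), ("1", 500), ("1", 900)]) == 0.0

    def test_fixture_hand_value_and_uncovered_dropped(self):
        prof = _profile((1, 100, 0.2), (201, 300, -0.4), (301, 400, 0.8))
        loci = [("1", 50), ("1", 250), ("1", 350), ("1", 150), ("1", 99)]
        # covered means: 0.2, -0.4, 0.8, (gap), 0.2
        vals = np.array([0.2, -0.4, 0.8, 0.2])
        assert cnv_std_at_snvs(prof, loci) == pytest.approx(float(np.std(vals)))

    def test_fewer_than_two_covered_is_missing(self):
        prof = _profile((1, 100, 0.2))
        assert cnv_std_at_snvs(prof, [("1", 50), ("1", 500)]) is None


class TestWgCnvStd:
    def test_hand_weighted_example(self):
        prof = _profile((1, 1, 0.0), (2, 4, 1.0))  # lengths 1 and 3
        assert wg_cnv_std(prof) == pytest.approx(np.sqrt(0.1875))

    def test_single_segment_zero(self):
        assert wg_cnv_std(_profile((1, 500, 0.7))) == 0.0

    def test_equal_lengths_match_unweighted_std(self, rng):
        means = rng.normal(size=6)
        prof = _profile(*[(1 + 100 * i, 100 + 100 * i, m) for i, m in enumerate(means)])
        assert wg_cnv_std(prof) == pytest.approx(float(np.std(means)))

    def test_matches_per_base_brute_force(self, rng):
        pos = 1
        triples = []
        for _ in range(8):
            length = int(rng.integers(50, 2000))
            triples.append((pos, pos + length - 1, float(rng.normal(0, 0.5))))
            pos += length
        prof = _profile(*triples)
        assert wg_cnv_std(prof) == pytest.approx(per_base_cnv_std(prof), abs=1e-9)


class TestFilterSnvsByCnv:
    def _sample(self, loci):
        return AFSample(
            "S", "C", "mutect",
            np.linspace(0.1, 0.5, len(loci)), loci,
        )

    def test_threshold_hand_trace(self):
        prof = _profile((1, 100, 0.1), (101, 200, -0.3), (201, 300, 0.25))
        out = filter_snvs_by_cnv(
            self._sample([("1", 50), ("1", 150), ("1", 250)]), prof
        )
        assert len(out.afs) == 1 and out.loci == [("1", 50)]

    def test_copy_neutral_and_infinite_threshold_identity(self):
        prof = _profile((1, 300, 0.0))
        loci = [("1", 10), ("1", 20), ("1", 30)]
        assert len(filter_snvs_by_cnv(self._sample(loci), prof).afs) == 3
        prof2 = _profile((1, 300, 5.0))
        out = filter_snvs_by_cnv(self._sample(loci), prof2, threshold=np.inf)
        assert len(out.afs) == 3

    def test_uncovered_loci_retained_and_counted(self):
        prof = _profile((1, 100, 0.0))
        out = filter_snvs_by_cnv(self._sample([("1", 50), ("1", 500)]), prof)
        assert len(out.afs) == 2
        assert out.n_uncovered == 1


class TestExtraStatistics:
    def test_symmetric_vector_zero_skew(self):
        stats = extra_statistics([0.1, 0.2, 0.3, 0.4, 0.5])
        assert stats["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_histogram_max_entropy(self):
        centers = (np.arange(40) + 0.5) * 0.025
        stats = extra_statistics(centers)
        assert stats["entropy"] == pytest.approx(np.log(40))

    def test_values_match_direct_recomputation(self, rng):
        x = rng.uniform(0.1, 0.6, size=200)
        stats = extra_statistics(x)
        assert stats["mean"] == pytest.approx(np.mean(x))
        assert stats["median"] == pytest.approx(np.median(x))
        assert stats["std"] == pytest.approx(np.std(x))
        assert stats["iqr"] == pytest.approx(
            np.percentile(x, 75) - np.percentile(x, 25)
        )
        assert stats["frac_gt_0.4"] == pytest.approx(np.mean(x > 0.4))
        assert stats["n_snvs"] == 200

    def test_tiny_inputs_mark_moments_missing(self):
        stats = extra_statistics([0.2, 0.3])
        assert stats["std"] is None and stats["skewness"] is None


class TestCnvAfCoupling:
    def test_cnv_dispersion_drives_af_dispersion(self, small_cohort):
        # when AF spread is driven by copy number, the two dispersions
        # correlate positively across the cohort
        from hetrobust.io_core import VariantCall  # noqa: F401

        truth = small_cohort.truth
        af_stds, cnv_stds = [], []
        for sid in small_cohort.sample_ids:
            calls = small_cohort.calls[sid]["mutect"]
            afs = np.array([c["af"] for c in calls])
            af_stds.append(np.std(afs))
            cnv_stds.append(
                truth.loc[truth.sample_id == sid, "wg_cnv_std"].item()
            )
        r = np.corrcoef(cnv_stds, af_stds)[0, 1]
        assert r > 0
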