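import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.stats import norm

import seedtrace as st
from seedtrace.mrd import DETECTION_SUPPORT_FLOOR, MrdMeasurement
from seedtrace.reference import revcomp

from oracles import oracle_count_seed_reads

SEED19 = "GAAATCAACGGGAAACTCC"  # the exact-match command-line example


class TestSeedCounting:
    def test_containment(self):
        assert st.count_seed_reads(["GAAATCAACGGGAAACTCCAT", "TTTT"], SEED19) == 1

    def test_reverse_strand_read_counted(self):
        read = "AT" + SEED19 + "GG"
        assert st.count_seed_reads([revcomp(read)], SEED19) == 1

    def test_read_counted_at_most_once(self):
        assert st.count_seed_reads([SEED19 + "AA" + SEED19], SEED19) == 1

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        reads=hst.lists(hst.text(alphabet="ACGT", min_size=1, max_size=40), max_size=20),
        seed=hst.text(alphabet="ACGT", min_size=2, max_size=6),
    )
    def test_matches_per_read_scan_oracle(self, reads, seed):
        assert st.count_seed_reads(reads, seed) == oracle_count_seed_reads(reads, seed)


class TestVaf:
    def test_ratio(self):
        assert st.compute_vaf(5, 10_000) == 0.0005

    def test_zero_numerator(self):
        assert st.compute_vaf(0, 10_000) == 0.0

    def test_assay_scale_depth(self):
        # one percent of the assay's average sequencing depth
        assert st.compute_vaf(8296, 829_568) == pytest.approx(0.01, rel=1e-3)

    def test_zero_total_undefined(self):
        with pytest.raises(ZeroDivisionError):
            st.compute_vaf(0, 0)


def _meas(vaf, total=1_000_000, sample="s1"):
    return MrdMeasurement(sample, f"itd{vaf}", round(vaf * total), total)


class TestAggregation:
    def test_multi_itd_sum(self):
        vafs = st.aggregate_sample_vaf([_meas(0.0005), _meas(0.00014)])
        assert vafs == pytest.approx(0.00064)

    def test_single_itd_identity(self):
        assert st.aggregate_sample_vaf([_meas(0.007)]) == pytest.approx(0.007)

    def test_capped_at_one(self):
        assert st.aggregate_sample_vaf([_meas(0.7), _meas(0.6)]) == 1.0

    def test_empty_is_zero(self):
        assert st.aggregate_sample_vaf([]) == 0.0

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError):
            st.aggregate_sample_vaf([_meas(0.1, sample="a"), _meas(0.1, sample="b")])

    def test_timepoint_takes_highest(self):
        assert st.pick_timepoint_vaf([0.001, 0.003]) == 0.003
        assert st.pick_timepoint_vaf([0.0, 0.0]) == 0.0


class TestCutoffs:
    def test_intermediate_vaf(self):
        out = st.classify_mrd(0.0005)
        assert out["calls"] == {0.02: False, 0.001: False, 0.0001: True, 0.00001: True}
        assert out["finest_positive"] == 0.00001

    def test_zero_negative_everywhere(self):
        out = st.classify_mrd(0.0)
        assert not any(out["calls"].values())
        assert out["finest_positive"] is None

    def test_boundary_is_strictly_greater(self):
        out = st.classify_mrd(0.001)
        assert out["calls"][0.001] is False

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            st.CutoffPolicy((0.001, 0.02))  # not decreasing
        with pytest.raises(ValueError):
            st.CutoffPolicy((1.5,))


class TestDetectionFlag:
    def test_floor_matches_discovery_rule(self):
        assert DETECTION_SUPPORT_FLOOR == 4
        assert not MrdMeasurement("s", "i", 3, 10_000).detected
        assert MrdMeasurement("s", "i", 4, 10_000).detected


class TestProbitLod:
    @staticmethod
    def _synthetic(rng, true_lod, slope, levels, replicates):
        a = norm.ppf(0.95) - slope * math.log10(true_lod)
        obs = []
        for v in levels:
            p = norm.cdf(a + slope * math.log10(v))
            obs.extend((v, bool(rng.random() < p)) for _ in range(replicates))
        return obs

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        true_lod = 6e-5
        obs = self._synthetic(rng, true_lod, 1.8, [3e-4, 1e-4, 6e-5, 3e-5, 1e-5, 3e-6], 50)
        res = st.probit_lod(obs)
        assert not res.separation_flag
        assert abs(res.lod95 - true_lod) / true_lod < 0.30
        assert res.ci_low <= res.lod95 <= res.ci_high

    def test_two_level_separation_bracket_midpoint(self):
        res = st.probit_lod([(1e-3, True), (1e-5, False)])
        assert res.separation_flag
        assert res.lod95 == pytest.approx(1e-4)
        assert (res.ci_low, res.ci_high) == (1e-5, 1e-3)

    def test_all_detected_brackets_below_lowest_level(self):
        res = st.probit_lod([(1e-3, True), (1e-4, True), (1e-5, True)])
        assert res.separation_flag
        assert res.lod95 == 1e-5
        assert res.ci_low == 0.0

    def test_zero_vaf_controls_excluded_from_fit(self):
        rng = np.random.default_rng(1)
        obs = self._synthetic(rng, 6e-5, 1.8, [3e-4, 1e-4, 3e-5, 1e-5], 40)
        with_blanks = obs + [(0.0, False)] * 20
        assert st.probit_lod(with_blanks).lod95 == st.probit_lod(obs).lod95
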