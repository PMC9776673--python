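import math

import numpy as np
import pytest

import seedtrace as st
from seedtrace.reference import revcomp
from seedtrace.simulate import WILD_TYPE


@pytest.fixture
def cfg30(flt3_ref, itd30):
    return st.SimConfig(
        ref=flt3_ref, itd_specs=((itd30, 0.5),), total_reads=1000, rng_seed=11
    )


class TestSampleGeneration:
    def test_counts_sum_to_total(self, cfg30):
        s = st.simulate_sample(cfg30)
        assert sum(s.truth.read_counts.values()) == 1000
        assert len(s.sequences) == 1000

    def test_wildtype_only_has_no_mutant_reads(self, flt3_ref):
        cfg = st.SimConfig(ref=flt3_ref, itd_specs=(), total_reads=500, rng_seed=0)
        s = st.simulate_sample(cfg)
        assert s.truth.read_counts == {WILD_TYPE: 500}

    def test_mutant_count_within_binomial_bound(self, cfg30):
        s = st.simulate_sample(cfg30)
        n = s.truth.read_counts[cfg30.itd_specs[0][0].label]
        assert abs(n - 500) <= 3 * math.sqrt(1000 * 0.25)

    def test_reads_are_template_ends(self, flt3_ref, itd30, cfg30):
        s = st.simulate_sample(st.SimConfig(ref=flt3_ref, itd_specs=((itd30, 0.5),), total_reads=200, per_base_error=0.0, rng_seed=2))
        mutant = st.reconstruct_mutant(flt3_ref, itd30)
        for i, seq in enumerate(s.sequences):
            tmpl = flt3_ref.sequence if s.origins[i] == 0 else mutant
            expect = tmpl[:150] if s.mates[i] == 1 else revcomp(tmpl[-150:])
            assert seq == expect

    def test_byte_identical_reproducibility(self, cfg30, tmp_path):
        a, b = st.simulate_sample(cfg30), st.simulate_sample(cfg30)
        assert a.sequences == b.sequences
        fa, fb = tmp_path / "a.fastq", tmp_path / "b.fastq"
        a.to_fastq(str(fa))
        b.to_fastq(str(fb))
        assert fa.read_bytes() == fb.read_bytes()

    def test_paired_requires_even_total(self, flt3_ref):
        with pytest.raises(ValueError):
            st.SimConfig(ref=flt3_ref, total_reads=999)

    def test_vafs_must_sum_below_one(self, flt3_ref, itd30):
        with pytest.raises(ValueError):
            st.SimConfig(ref=flt3_ref, itd_specs=((itd30, 0.7), (itd30, 0.5)))


class TestErrorInjection:
    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        assert st.inject_errors("ACGT" * 10, 0.0, rng) == "ACGT" * 10

    def test_rate_one_changes_every_base(self):
        rng = np.random.default_rng(0)
        s = "ACGT" * 25
        out = st.inject_errors(s, 1.0, rng)
        assert all(a != b for a, b in zip(s, out))
        assert set(out) <= set("ACGT")

    def test_substitution_count_within_binomial_bound(self):
        rng = np.random.default_rng(3)
        n, rate = 100_000, 0.01
        s = "A" * n
        out = st.inject_errors(s, rate, rng)
        k = sum(1 for c in out if c != "A")
        assert abs(k - n * rate) <= 3 * math.sqrt(n * rate * (1 - rate))


class TestDilutionSeries:
    def test_levels_must_decrease(self, cfg30):
        with pytest.raises(ValueError):
            st.simulate_dilution_series(cfg30, [0.01, 0.1])

    def test_realized_vafs_track_levels(self, flt3_ref, itd30):
        base = st.SimConfig(ref=flt3_ref, itd_specs=((itd30, 0.5),), total_reads=20_000, rng_seed=5)
        series = st.simulate_dilution_series(base, [0.5, 0.05, 0.005])
        realized = [s.truth.realized_vaf[itd30.label] for _, _, s in series]
        assert realized[0] > realized[1] > realized[2]
        for level, r in zip([0.5, 0.05, 0.005], realized):
            assert abs(r - level) <= 3 * math.sqrt(level * (1 - level) / 10_000)

    def test_adding_replicates_never_perturbs_earlier_samples(self, cfg30):
        one = st.simulate_dilution_series(cfg30, [0.5, 0.05], replicates=1)
        two = st.simulate_dilution_series(cfg30, [0.5, 0.05], replicates=2)
        for (l1, r1, s1), (l2, r2, s2) in zip(one, [x for x in two if x[1] == 0]):
            assert (l1, r1) == (l2, r2)
            assert s1.sequences == s2.sequences


class TestTruthSam:
    def test_truth_sam_parses_and_matches_reads(self, flt3_ref, itd30, tmp_path):
        import pysam

        cfg = st.SimConfig(ref=flt3_ref, itd_specs=((itd30, 0.3),), total_reads=100, per_base_error=0.0, rng_seed=4)
        s = st.simulate_sample(cfg)
        path = tmp_path / "truth.sam"
        s.to_sam(str(path))
        mutant = st.reconstruct_mutant(flt3_ref, itd30)
        n = 0
        with pysam.AlignmentFile(str(path), "r") as fh:
            for rec in fh:
                n += 1
                assert rec.get_tag("ot") in (WILD_TYPE, itd30.label)
                if not rec.is_unmapped:
                    assert rec.query_length == 150
                    if rec.get_tag("ot") == WILD_TYPE:
                        assert rec.cigarstring == "150M"
        assert n == 100

    def test_truth_cigar_marks_insert_within_read(self, flt3_ref, itd30, tmp_path):
        import pysam

        # anchor 70, 30 bp insert: mate 1 covers it entirely -> 71M30I49M
        cfg = st.SimConfig(ref=flt3_ref, itd_specs=((itd30, 1.0),), total_reads=10, per_base_error=0.0, rng_seed=4)
        s = st.simulate_sample(cfg)
        path = tmp_path / "truth.sam"
        s.to_sam(str(path))
        cigars = set()
        with pysam.AlignmentFile(str(path), "r") as fh:
            for rec in fh:
                if rec.is_read1:
                    cigars.add(rec.cigarstring)
        assert cigars == {"71M30I49M"}
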