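import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import seedtrace as st
from seedtrace.discovery import align_reads, extract_junction_events
from seedtrace.reference import revcomp

from oracles import oracle_align_score, oracle_best_strand_score

dna = hst.text(alphabet="ACGT", min_size=1)


def _consumed(cigar):
    return sum(n for op, n in cigar if op in "MIS")


class TestAlignExamples:
    def test_identity_read_is_all_match(self, toy_ref):
        aln = st.align_semi_global(toy_ref.sequence, toy_ref, min_score=0)
        assert aln.cigar == [("M", len(toy_ref))]
        assert aln.amplicon_start == 0
        assert aln.score == len(toy_ref)

    def test_internal_insertion_when_gap_beats_clip(self, flt3_ref):
        # 30 extra bases mid-read, long flanks on both sides: a single I
        refseq = flt3_ref.sequence
        read = refseq[:100] + "ACGTACGTACGTACGTACGTACGTACGTAC" + refseq[100:150]
        aln = st.align_semi_global(read, flt3_ref)
        assert [op for op, _ in aln.cigar] == ["M", "I", "M"]
        assert aln.cigar[1] == ("I", 30)

    def test_novel_tail_becomes_terminal_soft_clip(self, flt3_ref):
        read = flt3_ref.sequence[-30:] + "ATCGGATTACACCGGTTAAC" * 6
        aln = st.align_semi_global(read, flt3_ref)
        assert aln.cigar == [("M", 30), ("S", 120)]
        assert aln.amplicon_start == len(flt3_ref) - 30

    def test_reverse_strand_read(self, flt3_ref):
        read = revcomp(flt3_ref.sequence[50:180])
        aln = st.align_semi_global(read, flt3_ref)
        assert aln.is_reverse
        assert aln.cigar == [("M", 130)]
        assert aln.amplicon_start == 50

    def test_unalignable_read_signalled(self, flt3_ref):
        assert st.align_semi_global("ACGT" * 4, flt3_ref, min_score=20) is None

    def test_empty_read_rejected(self, flt3_ref):
        with pytest.raises(ValueError):
            st.align_semi_global("", flt3_ref)


class TestOracleEquivalence:
    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(data=hst.data())
    def test_score_matches_bruteforce_on_mutated_substrings(self, data):
        refseq = data.draw(hst.text(alphabet="ACGT", min_size=20, max_size=80))
        ref = st.build_amplicon_reference(refseq, "chrT", 1000, 1000 + len(refseq) - 1)
        i = data.draw(hst.integers(0, len(refseq) - 10))
        j = data.draw(hst.integers(i + 8, min(len(refseq), i + 60)))
        read = refseq[i:j]
        # optionally inject an insertion and a substitution
        ins = data.draw(hst.text(alphabet="ACGT", max_size=12))
        at = data.draw(hst.integers(0, len(read)))
        read = read[:at] + ins + read[at:]
        aln = st.align_semi_global(read, ref, both_strands=False, min_score=None)
        assert aln.score == oracle_align_score(read, refseq)
        assert _consumed(aln.cigar) == len(read)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        refseq=hst.text(alphabet="ACGT", min_size=10, max_size=80),
        read=hst.text(alphabet="ACGT", min_size=1, max_size=60),
    )
    def test_score_matches_bruteforce_on_random_reads(self, refseq, read):
        ref = st.build_amplicon_reference(refseq, "chrT", 1, len(refseq))
        aln = st.align_semi_global(read, ref, min_score=None)
        assert aln.score == oracle_best_strand_score(read, refseq)
        assert _consumed(aln.cigar) == len(read)


class TestBulkPath:
    def test_fast_path_agrees_with_dp_on_error_reads(self, flt3_ref):
        # the substitution-only shortcut may score a terminal mismatch as M
        # where the full DP clips it; placements agree and neither yields
        # junction candidates, which is the property the pipeline relies on
        rng = np.random.default_rng(0)
        refseq = flt3_ref.sequence
        reads = []
        for _ in range(50):
            s = st.inject_errors(refseq[:150], 0.01, rng)
            reads.append(("r", s))
            reads.append(("r", revcomp(st.inject_errors(refseq[58:], 0.01, rng))))
        for (rid, seq), aln in zip(reads, align_reads(reads, flt3_ref)):
            ref_aln = st.align_semi_global(seq, flt3_ref)
            assert aln is not None
            assert abs(aln.score - ref_aln.score) <= 6
            assert extract_junction_events([aln, ref_aln], flt3_ref) == []

    def test_error_free_wildtype_reads_are_all_match(self, flt3_ref):
        reads = [("a", flt3_ref.sequence[:150]), ("b", revcomp(flt3_ref.sequence[58:]))]
        for aln in align_reads(reads, flt3_ref):
            assert aln.cigar == [("M", 150)]
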