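import pytest

import seedtrace as st


@pytest.fixture(scope="session")
def flt3_ref():
    return st.default_flt3_reference()


@pytest.fixture(scope="session")
def toy_ref():
    # small reference used throughout structure/alignment unit tests
    return st.build_amplicon_reference("TTGACGTAGCATCC", "chr13", 100, 113)


def make_pure_dup(ref, origin_start: int, length: int) -> "st.ItdRecord":
    """Canonical pure tandem duplication copying ref[origin_start : origin_start+length]."""
    dup = ref.sequence[origin_start : origin_start + length]
    raw = st.ItdRecord(
        anchor_pos=origin_start + length - 1,
        inserted_seq=dup,
        duplication_seq=dup,
        spacer_seq="",
        origin_interval=(origin_start, origin_start + length),
        genomic_anchor=ref.to_genomic(origin_start + length - 1),
    )
    return st.left_align_itd(raw, ref)


def make_spacer_itd(ref, origin_start: int, dup_len: int, spacer: str) -> "st.ItdRecord":
    """Canonical ITD: duplication of ref[origin_start : origin_start+dup_len]
    preceding the origin, with a novel spacer between copy and origin."""
    return st.canonical_itd(
        ref,
        origin_start + dup_len - 1,
        spacer + ref.sequence[origin_start : origin_start + dup_len],
        min_duplication=min(dup_len, 6),
    )


@pytest.fixture(scope="session")
def itd30(flt3_ref):
    """The 30 bp tandem duplication used across end-to-end tests."""
    return make_pure_dup(flt3_ref, 71, 30)
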