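"""ITD structure: spacer + duplication decomposition and left-alignment.

An internal tandem duplication inserts a copy of a reference segment next
to its origin, often with a short novel "spacer" between the duplication
copy and the origin.  Decomposition identifies the duplicated reference
segment; left-alignment canonicalizes the insertion point so that
identical clones observed through different read placements unify into
one record.

Two equivalent presentations of the same event exist.  Reading the insert
at the 3' end of its origin, the insert is ``spacer + duplication`` with
the duplication copying the reference immediately 5' of the anchor (the
raw form produced by :func:`decompose_insertion`).  Because the last
inserted base then always equals the reference base at the anchor, the
insertion point can always be shifted left, and the leftmost placement
reads ``duplication + spacer`` with the duplication copying the reference
immediately 3' of the anchor — the mutant molecule then reads
duplication-copy, spacer, origin, matching the spacer's description as
sitting between the duplication and its origin.  The duplication and
spacer strings are identical in both presentations; only the anchor
bookkeeping differs.  Canonical records use the left-aligned form.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reference import AmpliconReference

__all__ = [
    "ItdRecord",
    "NotAnItdError",
    "decompose_insertion",
    "left_align_itd",
    "canonical_itd",
    "reconstruct_mutant",
    "MIN_DUPLICATION",
]

#: Shortest reference match accepted as a duplication; below this,
#: insert/reference homology is too likely to be coincidental.
MIN_DUPLICATION = 6


class NotAnItdError(ValueError):
    """The insertion has no adequate duplication of adjacent reference."""


@dataclass(frozen=True)
class ItdRecord:
    """An internal tandem duplication on the amplicon.

    The insert occurs *after* amplicon offset ``anchor_pos`` (0-based).
    In the raw form (``canonical=False``) ``inserted_seq == spacer_seq +
    duplication_seq`` and ``origin_interval`` (half-open) ends at
    ``anchor_pos + 1``; in the canonical left-aligned form
    (``canonical=True``) ``inserted_seq == duplication_seq + spacer_seq``
    and ``origin_interval`` starts at ``anchor_pos + 1``.
    """

    anchor_pos: int
    inserted_seq: str
    duplication_seq: str
    spacer_seq: str
    origin_interval: tuple[int, int]
    genomic_anchor: int
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.canonical:
            if self.duplication_seq + self.spacer_seq != self.inserted_seq:
                raise ValueError(
                    "canonical record requires inserted_seq == duplication + spacer"
                )
            if self.duplication_seq and self.origin_interval[0] != self.anchor_pos + 1:
                raise ValueError("canonical origin_interval must start at anchor + 1")
        else:
            if self.spacer_seq + self.duplication_seq != self.inserted_seq:
                raise ValueError("raw record requires inserted_seq == spacer + duplication")
            if self.origin_interval[1] != self.anchor_pos + 1:
                raise ValueError("raw origin_interval must end at anchor + 1")
        if self.origin_interval[1] - self.origin_interval[0] != len(self.duplication_seq):
            raise ValueError("origin_interval length must match duplication_seq")

    @property
    def itd_length(self) -> int:
        return len(self.inserted_seq)

    @property
    def in_frame(self) -> bool:
        """Whether the insertion preserves reading frame (length % 3 == 0).

        Clinically relevant FLT3 ITDs are in-frame; out-of-frame events
        are flagged, not suppressed.
        """
        return self.itd_length % 3 == 0

    @property
    def label(self) -> str:
        return f"itd_{self.genomic_anchor}_{self.itd_length}"


def decompose_insertion(
    ref: AmpliconReference,
    anchor_pos: int,
    inserted_seq: str,
    min_duplication: int = MIN_DUPLICATION,
) -> ItdRecord:
    """Split an inserted segment into spacer + duplication (raw form).

    The duplication is the longest suffix of ``inserted_seq`` equal to the
    reference substring ending at ``anchor_pos`` (inclusive); what remains
    in front is the spacer.  Raises :class:`NotAnItdError` when no suffix
    of at least ``min_duplication`` bases matches — the event is then a
    plain (non-ITD) insertion.
    """
    if not inserted_seq:
        raise ValueError("empty inserted sequence")
    if not 0 <= anchor_pos < len(ref):
        raise IndexError(f"anchor {anchor_pos} outside amplicon")
    refseq = ref.sequence
    max_k = min(len(inserted_seq), anchor_pos + 1)
    for k in range(max_k, min_duplication - 1, -1):
        if inserted_seq[-k:] == refseq[anchor_pos + 1 - k : anchor_pos + 1]:
            return ItdRecord(
                anchor_pos=anchor_pos,
                inserted_seq=inserted_seq,
                duplication_seq=inserted_seq[-k:],
                spacer_seq=inserted_seq[:-k],
                origin_interval=(anchor_pos + 1 - k, anchor_pos + 1),
                genomic_anchor=ref.to_genomic(anchor_pos),
            )
    raise NotAnItdError(
        f"no duplication of >= {min_duplication} bases ends at anchor {anchor_pos}"
    )


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def left_align_itd(record: ItdRecord, ref: AmpliconReference) -> ItdRecord:
    """Canonicalize an ITD by shifting its insertion point maximally left.

    While the last inserted base equals the reference base at the anchor,
    the insertion moves one base left by rotating the insert; every such
    placement yields the same mutant sequence.  At the leftmost placement
    the duplication is re-derived as the longest insert prefix matching
    the reference from ``anchor + 1`` on.  Idempotent; all equivalent
    placements of one event map to the same canonical record.
    """
    refseq = ref.sequence
    anchor = record.anchor_pos
    ins = record.inserted_seq
    while anchor >= 0 and ins[-1] == refseq[anchor]:
        ins = ins[-1] + ins[:-1]
        anchor -= 1
    if anchor == record.anchor_pos and record.canonical:
        return record
    dup_len = _common_prefix_len(ins, refseq[anchor + 1 :])
    return ItdRecord(
        anchor_pos=anchor,
        inserted_seq=ins,
        duplication_seq=ins[:dup_len],
        spacer_seq=ins[dup_len:],
        origin_interval=(anchor + 1, anchor + 1 + dup_len),
        genomic_anchor=ref.to_genomic(anchor) if anchor >= 0 else ref.genomic_start - 1,
        canonical=True,
    )


def canonical_itd(
    ref: AmpliconReference,
    anchor_pos: int,
    inserted_seq: str,
    min_duplication: int = MIN_DUPLICATION,
) -> ItdRecord:
    """Canonical ITD record straight from an observed (anchor, insert).

    Junction evidence arrives in whichever placement the aligner anchored
    (the duplication may sit 5' or 3' of the reported anchor); the mutant
    molecule it implies is the same either way, so the event is shifted to
    its leftmost placement first and the duplication read off there.  The
    minimum-duplication requirement is checked at the canonical placement;
    failures raise :class:`NotAnItdError` (a plain, non-ITD insertion).
    """
    if not inserted_seq:
        raise ValueError("empty inserted sequence")
    if not -1 <= anchor_pos < len(ref):
        raise IndexError(f"anchor {anchor_pos} outside amplicon")
    refseq = ref.sequence
    anchor, ins = anchor_pos, inserted_seq
    while anchor >= 0 and ins[-1] == refseq[anchor]:
        ins = ins[-1] + ins[:-1]
        anchor -= 1
    dup_len = _common_prefix_len(ins, refseq[anchor + 1 :])
    if dup_len < min_duplication:
        raise NotAnItdError(
            f"insert at anchor {anchor_pos} duplicates only {dup_len} adjacent "
            f"reference bases (< {min_duplication})"
        )
    return ItdRecord(
        anchor_pos=anchor,
        inserted_seq=ins,
        duplication_seq=ins[:dup_len],
        spacer_seq=ins[dup_len:],
        origin_interval=(anchor + 1, anchor + 1 + dup_len),
        genomic_anchor=ref.to_genomic(anchor) if anchor >= 0 else ref.genomic_start - 1,
        canonical=True,
    )


def reconstruct_mutant(ref: AmpliconReference, record: ItdRecord) -> str:
    """The full mutant amplicon implied by an ITD record."""
    a = record.anchor_pos
    return ref.sequence[: a + 1] + record.inserted_seq + ref.sequence[a + 1 :]
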