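"""Junction-seed design: the unique 12-20 bp tracer for one ITD.

Each ITD creates junction contexts absent from the wild-type amplicon.  A
seed is a 12-20 bp window of the mutant molecule that spans a junction
with enough overhang on both sides, occurs nowhere in the wild-type
amplicon or its reverse complement, and is then counted by exact substring
match to quantify the clone in any follow-up sample.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reference import AmpliconReference, revcomp
from .structure import ItdRecord, reconstruct_mutant

__all__ = [
    "SeedSequence",
    "NoUniqueSeedError",
    "enumerate_seed_candidates",
    "seed_occurrence_count",
    "select_seed",
    "design_seed",
    "MIN_SEED_LEN",
    "MAX_SEED_LEN",
    "MIN_JUNCTION_OVERHANG",
]

#: Seed size bounds chosen to balance sensitivity (shorter seeds lose
#: fewer reads to sequencing errors) against specificity.
MIN_SEED_LEN = 12
MAX_SEED_LEN = 20
#: Minimum bases on each side of the spanned junction, so that no single
#: terminal mismatch can turn a wild-type read into a seed match.
MIN_JUNCTION_OVERHANG = 4


class NoUniqueSeedError(ValueError):
    """No window spanning a junction is absent from the wild type."""


@dataclass(frozen=True)
class SeedSequence:
    """A junction-spanning tracer sequence for one ITD.

    ``junction_offset`` counts the seed bases falling left of the spanned
    junction; ``occurrences_in_wildtype`` covers the amplicon plus its
    reverse complement and is zero by construction.
    """

    bases: str
    itd_id: str
    junction_offset: int
    occurrences_in_wildtype: int
    occurrences_in_mutant: int

    def __len__(self) -> int:
        return len(self.bases)


def seed_occurrence_count(seed: str, subject: str, both_strands: bool = False) -> int:
    """Number of (possibly overlapping) exact occurrences of ``seed``.

    With ``both_strands`` the reverse complement of the subject is scanned
    too, so a seed straddling either strand is caught.
    """
    if not seed:
        raise ValueError("empty seed")

    def scan(text: str) -> int:
        n, start = 0, 0
        while True:
            i = text.find(seed, start)
            if i < 0:
                return n
            n += 1
            start = i + 1

    total = scan(subject)
    if both_strands:
        total += scan(revcomp(subject))
    return total


def enumerate_seed_candidates(
    record: ItdRecord,
    ref: AmpliconReference,
    min_len: int = MIN_SEED_LEN,
    max_len: int = MAX_SEED_LEN,
    min_overhang: int = MIN_JUNCTION_OVERHANG,
) -> list[SeedSequence]:
    """All windows of the mutant molecule usable as tracer seeds.

    A window qualifies when it overlaps the insert-start or insert-end
    junction with at least ``min_overhang`` bases on each side of that
    junction and never occurs in the wild-type amplicon (either strand).
    For a pure tandem duplication (empty spacer) both junction contexts
    exist and are enumerated the same way; uniqueness screening does the
    rest.  Sorted deterministically (position, then length).
    """
    mutant = reconstruct_mutant(ref, record)
    a = record.anchor_pos
    ins_len = record.itd_length
    junctions = (a + 1, a + 1 + ins_len)  # mutant offsets of the two novel joins
    windows: dict[tuple[int, int], int] = {}  # (start, length) -> junction
    for j in junctions:
        for length in range(min_len, max_len + 1):
            lo = max(0, j + min_overhang - length)
            hi = min(len(mutant) - length, j - min_overhang)
            for s in range(lo, hi + 1):
                key = (s, length)
                if key not in windows:
                    windows[key] = j
                else:
                    # window spans both junctions: keep the better-centred one
                    old = windows[key]
                    if abs((j - s) - length / 2) < abs((old - s) - length / 2):
                        windows[key] = j
    out: list[SeedSequence] = []
    for (s, length), j in sorted(windows.items()):
        bases = mutant[s : s + length]
        wt = seed_occurrence_count(bases, ref.sequence, both_strands=True)
        if wt:
            continue
        out.append(
            SeedSequence(
                bases=bases,
                itd_id=record.label,
                junction_offset=j - s,
                occurrences_in_wildtype=0,
                occurrences_in_mutant=seed_occurrence_count(bases, mutant),
            )
        )
    return out


def select_seed(candidates: list[SeedSequence]) -> SeedSequence:
    """Deterministic choice among qualifying windows.

    Shortest first (fewer bases exposed to sequencing error), then most
    centred on its junction, then lexicographically smallest.
    """
    if not candidates:
        raise NoUniqueSeedError("no unique junction-spanning window exists")
    return min(
        candidates,
        key=lambda c: (
            len(c.bases),
            abs(c.junction_offset - len(c.bases) / 2),
            c.bases,
        ),
    )


def design_seed(
    record: ItdRecord,
    ref: AmpliconReference,
    min_len: int = MIN_SEED_LEN,
    max_len: int = MAX_SEED_LEN,
) -> SeedSequence:
    """Enumerate and select the tracer seed for one ITD."""
    return select_seed(enumerate_seed_candidates(record, ref, min_len, max_len))
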