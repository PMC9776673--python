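"""Wild-type amplicon model: sequence, primer geometry and coordinate mapping.

The assay amplifies a single short locus (for FLT3, exons 14-15 on hg19
chr13:28,608,108-28,608,315, a 208 bp product).  Everything downstream works
in 0-based offsets into the amplicon; genomic positions (1-based, plus
strand) are used only for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "PrimerPair",
    "AmpliconReference",
    "build_amplicon_reference",
    "amplicon_length_from_primers",
    "to_genomic",
    "load_amplicon_fasta",
    "default_flt3_reference",
    "FLT3_PRIMERS",
    "revcomp",
]

_DNA = set("ACGT")
_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_RC)[::-1]


class ReferenceGeometryError(ValueError):
    """Inconsistent reference geometry or sequence content."""


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval; ``start``/``end`` may be given in
    either order (primer coordinates are conventionally printed 5'->3')."""

    chromosome: str
    start: int
    end: int

    @property
    def low(self) -> int:
        return min(self.start, self.end)

    @property
    def high(self) -> int:
        return max(self.start, self.end)

    def __len__(self) -> int:
        return self.high - self.low + 1


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse PCR primer binding sites.

    Both intervals must sit on one chromosome.  Typical primers are 15-40
    bases and do not overlap; violations are reported as warnings rather
    than errors so that degenerate geometries remain representable.
    """

    forward: GenomicInterval
    reverse: GenomicInterval

    def __post_init__(self) -> None:
        if self.forward.chromosome != self.reverse.chromosome:
            raise ReferenceGeometryError(
                "primer intervals on different chromosomes: "
                f"{self.forward.chromosome!r} vs {self.reverse.chromosome!r}"
            )
        for name, iv in (("forward", self.forward), ("reverse", self.reverse)):
            if not 15 <= len(iv) <= 40:
                warnings.warn(
                    f"{name} primer length {len(iv)} outside the usual 15-40 range",
                    stacklevel=2,
                )
        if not (self.forward.high < self.reverse.low or self.reverse.high < self.forward.low):
            warnings.warn("primer intervals overlap", stacklevel=2)


#: Printed primer coordinates of the FLT3 exon 14-15 assay (hg19).
FLT3_PRIMERS = PrimerPair(
    forward=GenomicInterval("chr13", 28_608_315, 28_608_296),
    reverse=GenomicInterval("chr13", 28_608_129, 28_608_108),
)


def amplicon_length_from_primers(primer: PrimerPair) -> int:
    """Inclusive span of the PCR product implied by a primer pair.

    The product runs from the lowest to the highest primer coordinate,
    ends included.
    """
    coords = [primer.forward.low, primer.forward.high, primer.reverse.low, primer.reverse.high]
    return max(coords) - min(coords) + 1


@dataclass(frozen=True)
class AmpliconReference:
    """The wild-type amplicon sequence anchored to genomic coordinates."""

    name: str
    chromosome: str
    genomic_start: int
    genomic_end: int
    sequence: str
    primer: PrimerPair | None = None
    genome_build: str = "hg19"

    def __post_init__(self) -> None:
        if self.genomic_end < self.genomic_start:
            raise ReferenceGeometryError("genomic_end precedes genomic_start")
        expected = self.genomic_end - self.genomic_start + 1
        if len(self.sequence) != expected:
            raise ReferenceGeometryError(
                f"sequence length {len(self.sequence)} does not match the "
                f"genomic span {self.chromosome}:{self.genomic_start}-"
                f"{self.genomic_end} ({expected} bp)"
            )
        bad = set(self.sequence) - _DNA
        if bad:
            raise ReferenceGeometryError(f"non-ACGT characters in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def reverse_complement(self) -> str:
        return revcomp(self.sequence)

    def to_genomic(self, amplicon_pos: int) -> int:
        """Map a 0-based amplicon offset to its 1-based genomic position."""
        if not 0 <= amplicon_pos < len(self.sequence):
            raise IndexError(
                f"amplicon offset {amplicon_pos} outside [0, {len(self.sequence)})"
            )
        return self.genomic_start + amplicon_pos


def build_amplicon_reference(
    sequence: str,
    chromosome: str,
    genomic_start: int,
    genomic_end: int,
    name: str = "amplicon",
    primer: PrimerPair | None = None,
) -> AmpliconReference:
    """Validate and assemble an :class:`AmpliconReference`."""
    if not sequence:
        raise ReferenceGeometryError("empty amplicon sequence")
    return AmpliconReference(
        name=name,
        chromosome=chromosome,
        genomic_start=genomic_start,
        genomic_end=genomic_end,
        sequence=sequence.upper(),
        primer=primer,
    )


def to_genomic(ref: AmpliconReference, amplicon_pos: int) -> int:
    """Functional alias for :meth:`AmpliconReference.to_genomic`."""
    return ref.to_genomic(amplicon_pos)


def load_amplicon_fasta(
    path: str | Path,
    chromosome: str,
    genomic_start: int,
    genomic_end: int,
    primer: PrimerPair | None = None,
) -> AmpliconReference:
    """Read a single-record FASTA and anchor it to genomic coordinates."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ReferenceGeometryError(f"expected exactly one FASTA record in {path}, found {len(records)}")
    rec = records[0]
    return build_amplicon_reference(
        str(rec.seq), chromosome, genomic_start, genomic_end, name=rec.id, primer=primer
    )


def default_flt3_reference() -> AmpliconReference:
    """The packaged FLT3 exon 14-15 amplicon.

    The base content is a synthetic stand-in with realistic composition
    (the true hg19 sequence is interchangeable: any 208 bp FASTA can be
    supplied); the coordinate frame is the assay's published one.
    """
    with resources.as_file(
        resources.files("seedtrace.data") / "flt3_amplicon_synthetic.fasta"
    ) as p:
        return load_amplicon_fasta(
            p,
            chromosome="chr13",
            genomic_start=28_608_108,
            genomic_end=28_608_315,
            primer=FLT3_PRIMERS,
        )
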