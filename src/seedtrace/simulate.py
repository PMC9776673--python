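"""Amplicon read simulator: dilution series with known ITDs and truth.

Emulates the assay's bench experiments: a wild-type amplicon spiked with
one or more ITD-bearing molecules at chosen molecular VAFs, sequenced as
paired reads with i.i.d. per-base substitution errors.  Amplicon
sequencing has no fragment-size selection, so every fragment is the whole
(wild-type or mutant) amplicon and the two mates read inward from its
ends; a long ITD is therefore visible as an internal insertion only when
it fits inside one mate, otherwise through soft clips — the reason the
bench assay moves to 300 bp reads for long duplications.

Error-free reads of one template are physically identical, so generation
shares one string per (template, mate) and only materializes the minority
of reads that carry errors; depths of 10^6 reads stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .reference import AmpliconReference, revcomp
from .structure import ItdRecord, reconstruct_mutant

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimSample",
    "simulate_sample",
    "simulate_dilution_series",
    "inject_errors",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
WILD_TYPE = "wt"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated sample.

    ``itd_specs`` pairs each ITD record with its molecular VAF (fraction
    of molecules carrying it).  Defaults mirror the assay: 150 bp paired
    reads, substitution error 0.1%/base, depth 10^5 for routine runs
    (10^6 matches the bench assay's average depth regime).
    """

    ref: AmpliconReference
    itd_specs: tuple[tuple[ItdRecord, float], ...] = ()
    total_reads: int = 100_000
    read_length: int = 150
    paired: bool = True
    per_base_error: float = 0.001
    rng_seed: int = 0
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.paired and self.total_reads % 2:
            raise ValueError("paired output requires an even total_reads")
        if self.read_length not in (150, 300):
            raise ValueError("read_length must be 150 or 300")
        if not 0.0 <= self.per_base_error <= 0.05:
            raise ValueError("per_base_error must lie in [0, 0.05]")
        total_vaf = sum(v for _, v in self.itd_specs)
        if total_vaf > 1.0 + 1e-12:
            raise ValueError("molecular VAFs sum above 1")
        if any(v < 0 for _, v in self.itd_specs):
            raise ValueError("negative molecular VAF")


@dataclass
class SimTruth:
    """Ground truth of one simulated sample."""

    origin_labels: list[str]  # per template: wt first, then ITD labels
    fragment_counts: dict[str, int]  # fragments per origin
    read_counts: dict[str, int]  # reads per origin
    total_reads: int
    realized_vaf: dict[str, float]  # read fraction per ITD origin

    def __post_init__(self) -> None:
        if sum(self.read_counts.values()) != self.total_reads:
            raise ValueError("read counts do not sum to total_reads")


@dataclass
class SimSample:
    """Reads plus truth.  Sequences are read-orientation strings (mate 2
    is the reverse complement of the fragment's far end)."""

    config: SimConfig
    sequences: list[str]
    origins: np.ndarray  # int16 code per read, index into truth.origin_labels
    mates: np.ndarray  # 1 or 2 per read
    truth: SimTruth

    def reads(self) -> Iterator[tuple[str, str]]:
        """(read_id, sequence) pairs; mates share a fragment stem."""
        sid = self.config.sample_id
        for i, seq in enumerate(self.sequences):
            frag = i // 2 if self.config.paired else i
            yield f"{sid}:frag{frag}/{self.mates[i]}", seq

    def to_fastq(self, path: str) -> None:
        """Standard 4-line FASTQ with constant Phred-40 quality."""
        with open(path, "w") as fh:
            for rid, seq in self.reads():
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")

    def to_sam(self, path: str) -> None:
        """Minimal truth SAM: correct POS/CIGAR per read, origin in the
        ``ot`` tag.  Reads falling entirely inside an insert are written
        unmapped."""
        ref = self.config.ref
        lines = [
            "@HD\tVN:1.6\tSO:unknown",
            f"@SQ\tSN:{ref.name}\tLN:{len(ref)}",
        ]
        records = {
            rec.label: rec for rec, _ in self.config.itd_specs
        }
        labels = self.truth.origin_labels
        for i, (rid, seq) in enumerate(self.reads()):
            origin = labels[self.origins[i]]
            mate = int(self.mates[i])
            rec = records.get(origin)
            tlen = len(ref) + (rec.itd_length if rec else 0)
            L = min(self.config.read_length, tlen)
            s, e = (0, L) if mate == 1 else (tlen - L, tlen)
            pos, cigar = _truth_cigar(rec, s, e, len(ref))
            flag = 1 | (64 if mate == 1 else 128) if self.config.paired else 0
            if mate == 2:
                flag |= 16
                sam_seq = revcomp(seq)
            else:
                sam_seq = seq
            if pos is None:
                flag |= 4
                lines.append(
                    f"{rid}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{sam_seq}\t*\tot:Z:{origin}"
                )
            else:
                lines.append(
                    f"{rid}\t{flag}\t{ref.name}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t"
                    f"{sam_seq}\t*\tot:Z:{origin}"
                )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _truth_cigar(
    rec: ItdRecord | None, s: int, e: int, ref_len: int
) -> tuple[int | None, str]:
    """POS (0-based) and CIGAR of the template slice [s, e) against the
    wild-type amplicon, with terminal insert overhangs as soft clips."""
    if rec is None:
        return s, f"{e - s}M"
    a, L = rec.anchor_pos, rec.itd_length
    ins_lo, ins_hi = a + 1, a + 1 + L
    m1 = max(0, min(e, ins_lo) - s)
    i_len = max(0, min(e, ins_hi) - max(s, ins_lo))
    m2 = max(0, e - max(s, ins_hi))
    parts: list[str] = []
    if m1:
        parts.append(f"{m1}M")
    if i_len:
        # an insert at a read end is a soft clip, not an insertion
        op = "I" if (m1 and m2) else "S"
        parts.append(f"{i_len}{op}")
    if m2:
        parts.append(f"{m2}M")
    if m1:
        pos = s
    elif m2:
        pos = max(s, ins_hi) - L
    else:
        return None, "*"
    return pos, "".join(parts)


def inject_errors(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Independently substitute each base with probability ``rate``,
    uniformly among the three alternatives.  Deterministic given the
    generator state; rate 0 is the identity and rate 1 changes every
    base."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0.0 or not sequence:
        return sequence
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return sequence
    _substitute(arr, hits, rng)
    return arr.tobytes().decode()


def _substitute(arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> None:
    """Replace bases at ``positions`` with a uniformly drawn different base."""
    cur = arr[positions]
    # map current base to its index in ACGT, pick one of the 3 others
    idx = np.zeros(cur.size, dtype=np.int8)
    for b, code in zip(_BASES, range(4)):
        idx[cur == b] = code
    offset = rng.integers(1, 4, size=cur.size)
    arr[positions] = _BASES[(idx + offset) % 4]


def _sample_seed(rng_seed: int, *spawn_key: int) -> np.random.Generator:
    """Derive a child generator from (seed, key...) stably, so adding
    replicates or levels never perturbs earlier samples."""
    return np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=spawn_key))


def simulate_sample(config: SimConfig, _rng: np.random.Generator | None = None) -> SimSample:
    """Draw one sample: origins multinomial over molecules, whole-amplicon
    fragments, inward paired mates, i.i.d. substitution errors."""
    rng = _rng if _rng is not None else _sample_seed(config.rng_seed)
    ref = config.ref
    labels = [WILD_TYPE] + [rec.label for rec, _ in config.itd_specs]
    templates = [ref.sequence] + [reconstruct_mutant(ref, rec) for rec, _ in config.itd_specs]
    vafs = [v for _, v in config.itd_specs]
    probs = [1.0 - sum(vafs)] + vafs

    n_units = config.total_reads // 2 if config.paired else config.total_reads
    unit_counts = rng.multinomial(n_units, probs)
    reads_per_unit = 2 if config.paired else 1

    sequences: list[str] = []
    origins = np.empty(config.total_reads, dtype=np.int16)
    mates = np.empty(config.total_reads, dtype=np.int8)
    pos = 0
    err = config.per_base_error
    for t_idx, (template, n_frag) in enumerate(zip(templates, unit_counts)):
        if n_frag == 0:
            continue
        L = min(config.read_length, len(template))
        mate_templates = [template[:L]]
        if config.paired:
            mate_templates.append(revcomp(template[-L:]))
        # interleave mates fragment by fragment
        block = _make_reads(mate_templates, n_frag, err, rng)
        n_reads = n_frag * reads_per_unit
        sequences.extend(block)
        origins[pos : pos + n_reads] = t_idx
        if config.paired:
            mates[pos : pos + n_reads] = np.tile([1, 2], n_frag)
        else:
            mates[pos : pos + n_reads] = 1
        pos += n_reads

    read_counts = {
        lab: int(c) * reads_per_unit for lab, c in zip(labels, unit_counts)
    }
    truth = SimTruth(
        origin_labels=labels,
        fragment_counts={lab: int(c) for lab, c in zip(labels, unit_counts)},
        read_counts=read_counts,
        total_reads=config.total_reads,
        realized_vaf={
            lab: read_counts[lab] / config.total_reads for lab in labels[1:]
        },
    )
    return SimSample(config=config, sequences=sequences, origins=origins, mates=mates, truth=truth)


def _make_reads(
    mate_templates: list[str], n_frag: int, err: float, rng: np.random.Generator
) -> list[str]:
    """n_frag fragments' reads, interleaved (m1, m2, m1, m2, ...).  Reads
    without errors share the template string object."""
    n_mates = len(mate_templates)
    out: list[str | None] = [None] * (n_frag * n_mates)
    for m, tmpl in enumerate(mate_templates):
        L = len(tmpl)
        if err > 0:
            k = rng.binomial(L, err, size=n_frag)
            hot = np.nonzero(k)[0]
        else:
            k = None
            hot = np.empty(0, dtype=int)
        for f in range(n_frag):
            out[f * n_mates + m] = tmpl
        if hot.size:
            base_arr = np.frombuffer(tmpl.encode(), dtype=np.uint8)
            for f in hot:
                arr = base_arr.copy()
                positions = rng.choice(L, size=k[f], replace=False)
                _substitute(arr, positions, rng)
                out[f * n_mates + m] = arr.tobytes().decode()
    return out  # type: ignore[return-value]


def simulate_dilution_series(
    base: SimConfig,
    vaf_levels: Sequence[float],
    replicates: int = 1,
) -> list[tuple[float, int, SimSample]]:
    """One sample per (level, replicate), scaling the base ITD mix so its
    total molecular VAF equals each level.  Sub-seeds derive stably from
    (seed, level index, replicate): earlier samples never change when more
    levels or replicates are added."""
    if list(vaf_levels) != sorted(vaf_levels, reverse=True):
        raise ValueError("vaf_levels must be strictly decreasing")
    if not base.itd_specs:
        raise ValueError("dilution series requires at least one ITD")
    base_total = sum(v for _, v in base.itd_specs)
    if base_total <= 0:
        raise ValueError("base ITD mix has zero total VAF")
    out = []
    for li, level in enumerate(vaf_levels):
        scale = level / base_total
        specs = tuple((rec, v * scale) for rec, v in base.itd_specs)
        for rep in range(replicates):
            cfg = SimConfig(
                ref=base.ref,
                itd_specs=specs,
                total_reads=base.total_reads,
                read_length=base.read_length,
                paired=base.paired,
                per_base_error=base.per_base_error,
                rng_seed=base.rng_seed,
                sample_id=f"{base.sample_id}_L{li}_r{rep}",
            )
            rng = _sample_seed(base.rng_seed, li, rep)
            out.append((level, rep, simulate_sample(cfg, _rng=rng)))
    return out
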