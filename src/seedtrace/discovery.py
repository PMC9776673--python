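"""Junction discovery: alignment, insertion/soft-clip extraction, clustering.

Reads are aligned to the amplicon with an affine-gap aligner that leaves
read ends free to soft-clip at any reference coordinate; internal tandem
duplications surface either as an internal ``I`` CIGAR operation (when
the whole insert fits inside the read and gap cost beats clipping) or as
a terminal soft clip (when the read ends inside the insert, or the
aligner matches through the first copy of the duplication and clips the
rest).  Clips are remapped onto the reference to reconstruct complete
inserts; candidates with identical inserted sequence at an identical
anchor are clustered, and a support/depth filter (more than 3 identical
reads out of more than 10,000) separates true ITDs from noise.

The bulk path uses an exact-substring shortcut and an edit-distance
pre-filter (edlib) so that the quadratic affine DP only runs on the small
minority of reads that actually contain indel evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import edlib
import numpy as np

from .reference import AmpliconReference, revcomp

__all__ = [
    "AlignedRead",
    "JunctionCandidate",
    "AlignScoring",
    "align_semi_global",
    "align_reads",
    "extract_junction_events",
    "cluster_and_filter",
    "read_sam",
    "MIN_SUPPORT",
    "MIN_TOTAL_READS",
    "MIN_CLIP",
]

#: "more than 3 reads of identical sequences" -> at least 4 supporting reads.
MIN_SUPPORT = 4
#: "out of more than 10,000 reads" -> at least 10,001 total reads.
MIN_TOTAL_READS = 10_001
#: Soft clips shorter than the minimum seed size cannot anchor a unique
#: junction and are treated as noise.
MIN_CLIP = 12


@dataclass(frozen=True)
class AlignScoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4  # score of the first base of a gap
    gap_extend: int = -1  # each additional base
    min_score: int = 20


DEFAULT_SCORING = AlignScoring()


@dataclass
class AlignedRead:
    """A read placed on the amplicon.

    ``sequence`` is stored in reference orientation (reverse-strand reads
    are reverse-complemented before alignment), so junction strings pulled
    from different strands agree literally.  ``cigar`` uses M/I/S/D with
    read-consuming lengths summing to ``len(sequence)``.
    """

    read_id: str
    sequence: str
    cigar: list[tuple[str, int]]
    amplicon_start: int
    score: float | None = None
    is_secondary: bool = False
    is_reverse: bool = False
    mate_index: int | None = None

    def __post_init__(self) -> None:
        consumed = sum(n for op, n in self.cigar if op in "MIS=X")
        if consumed != len(self.sequence):
            raise ValueError(
                f"CIGAR consumes {consumed} read bases but sequence has {len(self.sequence)}"
            )


@dataclass
class JunctionCandidate:
    """An inserted segment observed at one amplicon anchor.

    ``anchor_pos`` is the 0-based offset of the reference base immediately
    5' of the insertion point.  ``junction_string`` is the full inserted
    segment when reconstructable, or its read-truncated prefix/suffix for
    pure soft-clip evidence.
    """

    junction_string: str
    anchor_pos: int
    support: int = 1
    evidence_class: str = "insertion"  # insertion | softclip | mixed
    complete: bool = True  # False for raw read-truncated clip strings

    @property
    def key(self) -> tuple[str, int]:
        return (self.junction_string, self.anchor_pos)


# ---------------------------------------------------------------------------
# Affine-gap DP with free soft clips at both read ends
# ---------------------------------------------------------------------------

_NEG = -(10**9)


def _dp_matrices(read: str, ref: str, sc: AlignScoring):
    """Forward pass.  Returns (M, X, Y) score matrices and pointers.

    M: read base aligned to ref base (diagonal); X: gap in reference
    (insertion, consumes read); Y: gap in read (deletion, consumes ref).
    An alignment may start fresh at any cell and end at any cell; the
    unaligned read prefix/suffix becomes a soft clip, so clips are free at
    both read ends regardless of the reference coordinate (the semantics
    practical read aligners emit for amplicon data).  Gap of length L
    costs open + (L-1)*extend.
    """
    n, m = len(read), len(ref)
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    # pointer codes: 0=fresh start, 1=from M, 2=from X, 3=from Y
    Mp = np.zeros((n + 1, m + 1), dtype=np.int8)
    Xp = np.zeros((n + 1, m + 1), dtype=np.int8)
    # for Y the traceback needs the column where the gap opened
    Yfrom = np.zeros((n + 1, m + 1), dtype=np.int32)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    cols = np.arange(m + 1)
    ext = sc.gap_extend
    for i in range(1, n + 1):
        sub = np.where(ref_arr == read_arr[i - 1], sc.match, sc.mismatch)
        # M: diagonal from any state at (i-1, j-1), or a fresh start (0);
        # tie preference M > X > Y > start
        prevM, prevX, prevY = M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]
        best = np.maximum(np.maximum(np.maximum(prevM, prevX), prevY), 0)
        M[i, 1:] = best + sub
        Mp[i, 1:] = np.where(
            prevM == best, 1, np.where(prevX == best, 2, np.where(prevY == best, 3, 0))
        )
        # X: vertical gap (consume read base) from (i-1, j)
        openx = np.maximum(M[i - 1, :], Y[i - 1, :]) + sc.gap_open
        extx = X[i - 1, :] + ext
        X[i, :] = np.maximum(openx, extx)
        Xp[i, :] = np.where(extx >= openx, 2, np.where(M[i - 1, :] >= Y[i - 1, :], 1, 3))
        # Y: horizontal gap within row i, opened after some column j' < j:
        # Y[i,j] = max_{j'} S[j'] + open + (j-j'-1)*ext, via a prefix scan
        S = np.maximum(M[i], X[i])
        T = S - ext * cols
        run = np.maximum.accumulate(T)
        arg = np.maximum.accumulate(np.where(T == run, cols, 0))
        Y[i, 1:] = run[:-1] + ext * cols[1:] + (sc.gap_open - ext)
        Yfrom[i, 1:] = arg[:-1]
    return (M, X, Y), (Mp, Xp, Yfrom)


def _traceback(read: str, ref: str, mats, ptrs) -> tuple[int, list[tuple[str, int]], int]:
    """Walk back from the best-scoring cell.  Returns (score, cigar,
    amplicon_start)."""
    M, X, Y = mats
    Mp, Xp, Yfrom = ptrs
    n, m = len(read), len(ref)
    best_all = np.maximum(np.maximum(M, X), Y)
    flat = int(np.argmax(best_all))
    i, j = divmod(flat, m + 1)
    score = int(best_all[i, j])
    if score <= 0:  # nothing aligns better than clipping the whole read
        return 0, [("S", n)], 0
    ops: list[tuple[str, int]] = []
    if i < n:
        ops.append(("S", n - i))
    if M[i, j] == score:
        state = 1
    elif X[i, j] == score:
        state = 2
    else:
        state = 3
    while i > 0 and j > 0:
        if state == 1:
            p = Mp[i, j]
            ops.append(("M", 1))
            i, j = i - 1, j - 1
            if p == 0:
                break
            state = p
        elif state == 2:
            p = Xp[i, j]
            ops.append(("I", 1))
            i -= 1
            state = p
        else:
            j0 = int(Yfrom[i, j])
            ops.append(("D", j - j0))
            j = j0
            state = 1 if M[i, j] >= X[i, j] else 2
    start_j = j
    if i > 0:
        ops.append(("S", i))
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op, ln in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))
    return score, cigar, start_j


def _normalize_cigar(cigar: list[tuple[str, int]]) -> tuple[list[tuple[str, int]], int]:
    """Fold terminal insertions into soft clips and drop terminal deletions.

    Returns the cleaned CIGAR and the shift (ref bases) to add to
    amplicon_start when a leading deletion was dropped.
    """
    ops = list(cigar)
    shift = 0
    lead_s = 0
    while ops:
        op, ln = ops[0]
        if op in "SI":
            lead_s += ln
        elif op == "D":
            shift += ln
        else:
            break
        ops.pop(0)
    trail_s = 0
    while ops:
        op, ln = ops[-1]
        if op in "SI":
            trail_s += ln
        elif op != "D":
            break
        ops.pop()
    out: list[tuple[str, int]] = []
    if lead_s:
        out.append(("S", lead_s))
    out.extend(ops)
    if trail_s:
        out.append(("S", trail_s))
    return out, shift


def _align_one_strand(
    read: str, ref: str, scoring: AlignScoring
) -> tuple[int, list[tuple[str, int]], int]:
    mats, ptrs = _dp_matrices(read, ref, scoring)
    score, cigar, start = _traceback(read, ref, mats, ptrs)
    cigar, shift = _normalize_cigar(cigar)
    return score, cigar, start + shift


def align_semi_global(
    read_sequence: str,
    ref: AmpliconReference,
    scoring: AlignScoring = DEFAULT_SCORING,
    both_strands: bool = True,
    read_id: str = "read",
    min_score: int | None = -1,
) -> AlignedRead | None:
    """Best-scoring semi-global alignment of one read against the amplicon.

    End gaps are free on both sequences, so reads may start and end
    anywhere on the amplicon and terminal read overhangs become soft clips.
    A contiguous inserted segment that fits within the read appears as a
    single I operation; inserts truncated by the read end appear as a
    terminal S.  With ``both_strands`` the reverse complement is tried too
    and the higher-scoring orientation kept (forward wins ties).

    Returns ``None`` when the best score falls below ``min_score``
    (default: the scoring scheme's floor; pass ``None`` to disable), the
    unalignable-read signal.
    """
    if not read_sequence:
        raise ValueError("empty read")
    if min_score == -1:
        min_score = scoring.min_score
    elif min_score is None:
        min_score = _NEG
    fwd = _align_one_strand(read_sequence, ref.sequence, scoring)
    if both_strands:
        rc = revcomp(read_sequence)
        rev = _align_one_strand(rc, ref.sequence, scoring)
    else:
        rev = None
    if rev is not None and rev[0] > fwd[0]:
        score, cigar, start = rev
        seq, is_rev = rc, True
    else:
        score, cigar, start = fwd
        seq, is_rev = read_sequence, False
    if score < min_score:
        return None
    return AlignedRead(
        read_id=read_id,
        sequence=seq,
        cigar=cigar,
        amplicon_start=start,
        score=score,
        is_reverse=is_rev,
    )


# ---------------------------------------------------------------------------
# Bulk alignment with fast paths
# ---------------------------------------------------------------------------

def _edlib_no_indel(read: str, ref: str) -> tuple[int, int] | None:
    """Edit-distance screen.  Returns (distance, target_start) when the
    optimal unit-cost alignment is substitution-only and low-distance,
    else None (candidate for the full affine DP)."""
    res = edlib.align(read, ref, mode="HW", task="path")
    dist = res["editDistance"]
    if dist < 0 or dist > max(3, len(read) // 25):
        return None
    cig = res["cigar"] or ""
    if "I" in cig or "D" in cig:
        return None
    return dist, res["locations"][0][0]


def align_reads(
    reads: Iterable[tuple[str, str]],
    ref: AmpliconReference,
    scoring: AlignScoring = DEFAULT_SCORING,
    drop_unalignable: bool = False,
) -> Iterator[AlignedRead | None]:
    """Align (read_id, sequence) pairs, yielding one result per read.

    Substitution-only reads are resolved by exact search or the edlib
    screen; only reads with indel evidence reach the affine DP.  Yields
    ``None`` for unalignable reads unless ``drop_unalignable``.
    """
    refseq = ref.sequence
    cache: dict[str, AlignedRead | None] = {}
    for read_id, seq in reads:
        # error-free reads of one template are literally identical, so the
        # bulk path memoizes per distinct sequence; the shared AlignedRead
        # keeps its first read_id (extraction does not use it).
        if seq in cache:
            aln = cache[seq]
        else:
            aln = _fast_align(read_id, seq, ref, refseq, scoring)
            cache[seq] = aln
        if aln is None and drop_unalignable:
            continue
        yield aln


def _fast_align(
    read_id: str,
    seq: str,
    ref: AmpliconReference,
    refseq: str,
    scoring: AlignScoring,
) -> AlignedRead | None:
    pos = refseq.find(seq)
    if pos >= 0:
        return AlignedRead(read_id, seq, [("M", len(seq))], pos, score=len(seq))
    rc = revcomp(seq)
    pos = refseq.find(rc)
    if pos >= 0:
        return AlignedRead(read_id, rc, [("M", len(rc))], pos, score=len(rc), is_reverse=True)
    hit_f = _edlib_no_indel(seq, refseq)
    hit_r = _edlib_no_indel(rc, refseq)
    if hit_f is not None and (hit_r is None or hit_f[0] <= hit_r[0]):
        dist, start = hit_f
        score = len(seq) + dist * (scoring.mismatch - scoring.match)
        if score < scoring.min_score:
            return None
        return AlignedRead(read_id, seq, [("M", len(seq))], start, score=score)
    if hit_r is not None:
        dist, start = hit_r
        score = len(rc) + dist * (scoring.mismatch - scoring.match)
        if score < scoring.min_score:
            return None
        return AlignedRead(read_id, rc, [("M", len(rc))], start, score=score, is_reverse=True)
    return align_semi_global(seq, ref, scoring=scoring, read_id=read_id)


# ---------------------------------------------------------------------------
# Junction extraction
# ---------------------------------------------------------------------------

def _resolve_trailing_clip(clip: str, anchor: int, refseq: str, min_match: int) -> str | None:
    """Reconstruct the full inserted segment from a trailing soft clip.

    The clip follows reference that aligned through ``anchor``.  Take the
    longest clip suffix that occurs in the reference at some position
    ``p <= anchor + 1`` (the point where the molecule resumes reference
    sequence); the bases in front of it are novel (spacer) and the skipped
    stretch ``ref[p : anchor+1]`` is the duplicated segment, so the insert
    is ``novel + ref[p : anchor+1]``.  ``p == anchor + 1`` is the plain
    case of a read running past the insert into downstream reference.
    Duplication-copy overruns (the aligner matching through the first copy
    of a tandem duplication) resolve the same way.  Returns None when no
    suffix of >= ``min_match`` bases maps."""
    max_w = min(len(clip), len(refseq))
    for w in range(max_w, min_match - 1, -1):
        suf = clip[len(clip) - w :]
        p = refseq.rfind(suf, 0, anchor + 1 + w)  # rightmost start p <= anchor+1
        if p >= 0:
            ins = clip[: len(clip) - w] + refseq[p : anchor + 1]
            if ins:
                return ins
    return None


def _resolve_leading_clip(clip: str, start: int, refseq: str, min_match: int) -> str | None:
    """Mirror case for a leading soft clip before an alignment starting at
    reference offset ``start``.

    Either the clip begins with the reference flank ending at ``start``
    (the read covers the complete insert: return the remainder), or its
    longest prefix occurs in the reference at ``p >= start`` (the read
    starts inside the insert of a duplication whose copy begins at
    ``start``: the insert is ``ref[start : p+w] + remainder``)."""
    max_w = min(len(clip), len(refseq))
    for w in range(max_w, min_match - 1, -1):
        pre = clip[:w]
        if w <= start and w < len(clip) and refseq[start - w : start] == pre:
            return clip[w:]
        p = refseq.find(pre, start)
        if p >= 0:
            ins = refseq[start : p + w] + clip[w:]
            if ins:
                return ins
    return None


def extract_junction_events(
    alignments: Iterable[AlignedRead | None],
    ref: AmpliconReference,
    min_clip: int = MIN_CLIP,
    rescue_min_match: int = 8,
) -> list[JunctionCandidate]:
    """Pull one junction candidate per insertion/soft-clip event.

    Internal I operations yield the inserted bases directly.  A read side
    that carries a soft clip is collapsed to the bases outside the
    principal (longest) match run and remapped onto the reference to
    reconstruct the complete inserted segment; each reconstruction is
    validated by requiring the read to be a substring of the implied
    mutant molecule, with small junction-boundary shifts retried because
    coincidental matches can drag the aligner's match run a few bases
    across the true junction.  When no reconstruction validates, the raw
    clipped bases are emitted as a truncated-insert candidate.  Secondary
    alignments and unaligned reads contribute nothing.
    """
    refseq = ref.sequence
    out: list[JunctionCandidate] = []
    memo: dict[tuple[str, str], JunctionCandidate | None] = {}
    for aln in alignments:
        if aln is None or aln.is_secondary:
            continue
        spans = _cigar_spans(aln)  # (op, len, read_off, ref_off) per op
        m_idx = [k for k, (op, _, _, _) in enumerate(spans) if op == "M"]
        if not m_idx:
            continue
        principal = max(m_idx, key=lambda k: (spans[k][1], -k))
        lead, trail = spans[:principal], spans[principal + 1 :]

        if any(op == "S" for op, *_ in lead):
            clip_len = sum(ln for op, ln, _, _ in lead if op in "MIS")
            start = spans[principal][3]
            if clip_len >= min_clip and start >= 1:
                key = (aln.sequence, "L")
                if key not in memo:
                    memo[key] = _leading_candidate(
                        aln.sequence, clip_len, start, refseq, rescue_min_match
                    )
                if memo[key] is not None:
                    out.append(replace(memo[key]))
        else:
            out.extend(_internal_insertions(aln, lead))

        if any(op == "S" for op, *_ in trail):
            first = trail[0]
            clip_start = first[2]
            anchor = spans[principal][3] + spans[principal][1] - 1
            if len(aln.sequence) - clip_start >= min_clip and anchor >= 0:
                key = (aln.sequence, "T")
                if key not in memo:
                    memo[key] = _trailing_candidate(
                        aln.sequence, clip_start, anchor, refseq, rescue_min_match
                    )
                if memo[key] is not None:
                    out.append(replace(memo[key]))
        else:
            out.extend(_internal_insertions(aln, trail))
    return out


def _cigar_spans(aln: AlignedRead) -> list[tuple[str, int, int, int]]:
    spans = []
    i, j = 0, aln.amplicon_start
    for op, ln in aln.cigar:
        spans.append((op, ln, i, j))
        if op in "MIS":
            i += ln
        if op in "MD":
            j += ln
    return spans


def _internal_insertions(aln: AlignedRead, spans) -> list[JunctionCandidate]:
    out = []
    for op, ln, i, j in spans:
        if op == "I" and j >= 1:
            out.append(JunctionCandidate(aln.sequence[i : i + ln], j - 1, 1, "insertion"))
    return out


_MAX_BOUNDARY_SHIFT = 6
#: matched bases adjacent to the clip required to confirm a junction placement
_VALIDATE_PAD = 12


def _leading_candidate(
    seq: str, clip_len: int, start: int, refseq: str, min_match: int
) -> JunctionCandidate | None:
    """Resolve a leading clip, retrying with the junction shifted a few
    bases into the match run; keep the first reconstruction whose implied
    mutant contains the read."""
    for t in range(_MAX_BOUNDARY_SHIFT + 1):
        s = start + t
        if clip_len + t >= len(seq) or s >= len(refseq):
            break
        ins = _resolve_leading_clip(seq[: clip_len + t], s, refseq, min_match)
        if ins is None:
            continue
        mutant = refseq[:s] + ins + refseq[s:]
        # junction-local check: the clip plus the next stretch of matched
        # bases must exist in the implied mutant (tolerates errors far
        # from the junction, rejects misplaced junctions)
        window = seq[: clip_len + t + _VALIDATE_PAD]
        if window in mutant:
            return JunctionCandidate(ins, s - 1, 1, "softclip")
    return JunctionCandidate(seq[:clip_len], start - 1, 1, "softclip", complete=False)


def _trailing_candidate(
    seq: str, clip_start: int, anchor: int, refseq: str, min_match: int
) -> JunctionCandidate | None:
    for t in range(_MAX_BOUNDARY_SHIFT + 1):
        a = anchor - t
        if clip_start - t <= 0 or a < 0:
            break
        ins = _resolve_trailing_clip(seq[clip_start - t :], a, refseq, min_match)
        if ins is None:
            continue
        mutant = refseq[: a + 1] + ins + refseq[a + 1 :]
        window = seq[max(0, clip_start - t - _VALIDATE_PAD) :]
        if window in mutant:
            return JunctionCandidate(ins, a, 1, "softclip")
    return JunctionCandidate(seq[clip_start:], anchor, 1, "softclip", complete=False)


def cluster_and_filter(
    candidates: Sequence[JunctionCandidate],
    total_reads: int,
    min_support: int = MIN_SUPPORT,
    min_total: int = MIN_TOTAL_READS,
) -> list[JunctionCandidate]:
    """Cluster by exact (junction_string, anchor) identity and filter.

    Truncated soft-clip strings that are proper prefixes or suffixes of a
    longer insertion-backed candidate at the same anchor are folded into
    that candidate before the support filter is applied.  A group survives
    when its merged support is at least ``min_support`` (strict "> 3
    identical reads") and the sample depth is at least ``min_total``
    (strict "> 10,000 reads").  Output is ordered by support descending,
    then anchor, then sequence, so results are independent of input order.
    """
    if total_reads < 0:
        raise ValueError("total_reads must be non-negative")
    groups: dict[tuple[str, int], JunctionCandidate] = {}
    for c in candidates:
        g = groups.get(c.key)
        if g is None:
            groups[c.key] = JunctionCandidate(
                c.junction_string, c.anchor_pos, c.support, c.evidence_class, c.complete
            )
        else:
            g.support += c.support
            g.complete = g.complete or c.complete
            if g.evidence_class != c.evidence_class:
                g.evidence_class = "mixed"

    # fold truncated clip strings into the longer candidate they prefix or
    # suffix at the same anchor (reads ending inside the insert truncate it)
    for g in sorted(groups.values(), key=lambda g: len(g.junction_string)):
        if g.complete:
            continue
        hosts = [
            h
            for h in groups.values()
            if h.complete
            and h.anchor_pos == g.anchor_pos
            and h.support >= min_support  # never absorb into noise-level groups
            and len(h.junction_string) > len(g.junction_string)
            and (
                h.junction_string.startswith(g.junction_string)
                or h.junction_string.endswith(g.junction_string)
            )
        ]
        if hosts:
            hosts.sort(key=lambda h: (-len(h.junction_string), -h.support, h.junction_string))
            hosts[0].support += g.support
            hosts[0].evidence_class = "mixed"
            del groups[g.key]

    kept = [
        g
        for g in groups.values()
        if g.support >= min_support and total_reads >= min_total
    ]
    kept.sort(key=lambda g: (-g.support, g.anchor_pos, g.junction_string))
    return kept


# ---------------------------------------------------------------------------
# SAM input
# ---------------------------------------------------------------------------

def read_sam(path: str) -> Iterator[AlignedRead]:
    """Stream primary alignments from a SAM file as :class:`AlignedRead`.

    CIGARs are trusted as given (=/X folded into M); secondary and
    supplementary records are marked so downstream counting can skip them.
    POS is interpreted against the amplicon as reference, so the SAM must
    be aligned to the amplicon sequence itself.
    """
    import pysam

    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None or rec.cigartuples is None:
                continue
            opmap = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}
            cigar: list[tuple[str, int]] = []
            skip = False
            for code, ln in rec.cigartuples:
                op = opmap.get(code)
                if op is None:
                    skip = True  # N/H/P not meaningful on an amplicon
                    break
                if cigar and cigar[-1][0] == op:
                    cigar[-1] = (op, cigar[-1][1] + ln)
                else:
                    cigar.append((op, ln))
            if skip:
                continue
            yield AlignedRead(
                read_id=rec.query_name,
                sequence=rec.query_sequence,
                cigar=cigar,
                amplicon_start=rec.reference_start,
                is_secondary=rec.is_secondary or rec.is_supplementary,
                is_reverse=rec.is_reverse,
                mate_index=1 if rec.is_read1 else (2 if rec.is_read2 else None),
            )
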