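"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately naive (full dynamic-programming tables,
regex/positional scans, exhaustive placement enumeration) and shares no
code with the package implementation it checks.
"""

from __future__ import annotations

NEG = float("-inf")

_RC = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def oracle_align_score(
    read: str,
    ref: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -4,
    gap_extend: int = -1,
) -> int:
    """Best local-with-free-clip affine alignment score, plain-Python DP.

    A gap of length L costs gap_open + (L-1)*gap_extend; the alignment may
    start and end anywhere (unaligned read ends are free soft clips); the
    empty alignment scores 0.
    """
    n, m = len(read), len(ref)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if read[i - 1] == ref[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0)
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend, Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, X[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return int(best)


def oracle_best_strand_score(read: str, ref: str) -> int:
    return max(oracle_align_score(read, ref), oracle_align_score(rc(read), ref))


def oracle_occurrences(needle: str, haystack: str) -> int:
    """Overlapping occurrence count by positional scan."""
    return sum(
        1
        for i in range(len(haystack) - len(needle) + 1)
        if haystack[i : i + len(needle)] == needle
    )


def oracle_count_seed_reads(reads: list[str], seed: str) -> int:
    return sum(
        1 for r in reads if oracle_occurrences(seed, r) > 0 or oracle_occurrences(seed, rc(r)) > 0
    )


def oracle_longest_suffix_dup(refseq: str, anchor: int, ins: str) -> int:
    """Longest k with ins[-k:] == refseq ending at anchor (inclusive)."""
    best = 0
    for k in range(1, min(len(ins), anchor + 1) + 1):
        if ins[-k:] == refseq[anchor + 1 - k : anchor + 1]:
            best = k
    return best


def oracle_equivalent_placements(refseq: str, mutant: str) -> list[tuple[int, str]]:
    """All (anchor, insert) placements whose single insertion reproduces
    ``mutant`` from ``refseq``, by exhaustive string equality."""
    L = len(mutant) - len(refseq)
    assert L > 0
    out = []
    for anchor in range(-1, len(refseq)):
        ins = mutant[anchor + 1 : anchor + 1 + L]
        if refseq[: anchor + 1] + ins + refseq[anchor + 1 :] == mutant:
            out.append((anchor, ins))
    return out
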