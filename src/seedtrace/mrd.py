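"""MRD quantification: exact seed counting, VAF, cut-offs, probit LOD.

The measurable-residual-disease level of a clone is the fraction of reads
containing its tracer seed (either strand), mirroring the command-line
idiom ``samtools view bam | grep SEED | wc -l`` over the total read
count.  Multi-ITD samples are aggregated by summing per-ITD VAFs; repeat
tests at one timepoint take the maximum.  The assay's limit of detection
is the VAF at which a probit regression of detection probability on
log10(VAF) reaches 95%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .reference import revcomp
from .seeds import SeedSequence

__all__ = [
    "MrdMeasurement",
    "CutoffPolicy",
    "ProbitLodResult",
    "count_seed_reads",
    "compute_vaf",
    "aggregate_sample_vaf",
    "pick_timepoint_vaf",
    "classify_mrd",
    "probit_lod",
    "DETECTION_SUPPORT_FLOOR",
]

#: Reads containing the seed needed to call a clone "detected" — the same
#: strict "> 3 identical reads" rule used at discovery.
DETECTION_SUPPORT_FLOOR = 4

#: Default cut-off ladder as VAF fractions: 2% (fragment-analysis limit),
#: 0.1%, 0.01%, 0.001%.
DEFAULT_CUTOFFS = (0.02, 0.001, 0.0001, 0.00001)


@dataclass(frozen=True)
class CutoffPolicy:
    """Ordered MRD cut-offs (VAF fractions, strictly decreasing)."""

    thresholds: tuple[float, ...] = DEFAULT_CUTOFFS

    def __post_init__(self) -> None:
        ts = self.thresholds
        if not ts:
            raise ValueError("at least one threshold required")
        if any(not 0 < t < 1 for t in ts):
            raise ValueError("thresholds must lie in (0, 1)")
        if any(a <= b for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly decreasing")


@dataclass
class MrdMeasurement:
    """Seed-count quantification of one ITD in one sample."""

    sample_id: str
    itd_id: str
    seed_read_count: int
    total_read_count: int
    timepoint: str | None = None

    @property
    def vaf(self) -> float:
        return compute_vaf(self.seed_read_count, self.total_read_count)

    @property
    def detected(self) -> bool:
        return self.seed_read_count >= DETECTION_SUPPORT_FLOOR


def count_seed_reads(reads: Iterable[str], seed: SeedSequence | str) -> int:
    """Reads containing the seed exactly, on either strand, each read
    counted at most once.  Paired mates are independent reads; the caller
    is responsible for excluding secondary alignment records."""
    bases = seed.bases if isinstance(seed, SeedSequence) else seed
    if not bases:
        raise ValueError("empty seed")
    rc = revcomp(bases)
    return sum(1 for r in reads if bases in r or rc in r)


def compute_vaf(seed_read_count: int, total_read_count: int) -> float:
    """Variant allele frequency: seed reads over total reads."""
    if total_read_count <= 0:
        raise ZeroDivisionError("total read count must be positive to define a VAF")
    if not 0 <= seed_read_count <= total_read_count:
        raise ValueError("seed read count outside [0, total]")
    return seed_read_count / total_read_count


def aggregate_sample_vaf(measurements: Sequence[MrdMeasurement]) -> float:
    """Sample-level VAF: the sum over clones present in one sample, capped
    at 1.  An empty list means nothing was traced: VAF 0."""
    if not measurements:
        return 0.0
    ids = {m.sample_id for m in measurements}
    if len(ids) > 1:
        raise ValueError(f"measurements span multiple samples: {sorted(ids)}")
    return min(1.0, sum(m.vaf for m in measurements))


def pick_timepoint_vaf(aggregated_vafs: Sequence[float]) -> float:
    """Across repeat tests at one timepoint, the highest VAF defines the
    MRD level."""
    if not aggregated_vafs:
        raise ValueError("no measurements at timepoint")
    return max(aggregated_vafs)


def classify_mrd(vaf: float, policy: CutoffPolicy = CutoffPolicy()) -> dict:
    """Positive/negative call at each cut-off (strictly greater-than) and
    the finest threshold exceeded, if any."""
    calls = {t: vaf > t for t in policy.thresholds}
    exceeded = [t for t in policy.thresholds if vaf > t]
    return {
        "vaf": vaf,
        "calls": calls,
        "finest_positive": min(exceeded) if exceeded else None,
    }


@dataclass(frozen=True)
class ProbitLodResult:
    """95%-probability limit of detection from a dilution series."""

    lod95: float
    ci_low: float
    ci_high: float
    n_levels: int
    separation_flag: bool
    intercept: float | None = None
    slope: float | None = None


def _separation_bracket(levels_sorted: list[tuple[float, float]]) -> tuple[float, float] | None:
    """If every level is all-miss or all-hit with misses strictly below
    hits, return (highest all-miss level, lowest all-hit level)."""
    rates = [r for _, r in levels_sorted]
    if any(0.0 < r < 1.0 for r in rates):
        return None
    # detection must be monotone: no hit level below a miss level
    seen_hit = False
    for _, r in levels_sorted:
        if r == 1.0:
            seen_hit = True
        elif seen_hit:
            return None
    misses = [v for v, r in levels_sorted if r == 0.0]
    hits = [v for v, r in levels_sorted if r == 1.0]
    if not hits:
        return None
    lo = max(misses) if misses else 0.0
    return lo, min(hits)


def probit_lod(
    observations: Sequence[tuple[float, bool]],
    probability: float = 0.95,
) -> ProbitLodResult:
    """Fit detection probability = Phi(a + b*log10(VAF)) and invert at
    ``probability``.

    ``observations`` are (expected VAF fraction, detected) pairs across a
    dilution series.  Zero-VAF negative controls never enter the
    regression (log10 undefined); they only confirm the blank is negative.
    Perfectly separated data cannot be fit: the LOD is then reported as
    the log-scale midpoint between the highest all-miss and lowest all-hit
    levels, with that bracket as the interval and ``separation_flag`` set.
    The confidence interval of a regular fit is a delta-method 95% band on
    log10(LOD), back-transformed.
    """
    pos = [(v, d) for v, d in observations if v > 0]
    if not pos:
        raise ValueError("no positive-VAF observations")
    by_level: dict[float, list[bool]] = {}
    for v, d in pos:
        by_level.setdefault(v, []).append(bool(d))
    levels_sorted = sorted((v, float(np.mean(ds))) for v, ds in by_level.items())
    n_levels = len(levels_sorted)

    bracket = _separation_bracket(levels_sorted)
    if bracket is not None or n_levels < 2:
        if bracket is None:  # single mixed level: no usable bracket either
            v = levels_sorted[0][0]
            return ProbitLodResult(v, v, v, n_levels, True)
        lo, hi = bracket
        if lo <= 0:  # everything detected: LOD is below the lowest level
            return ProbitLodResult(hi, 0.0, hi, n_levels, True)
        mid = 10 ** ((math.log10(lo) + math.log10(hi)) / 2)
        return ProbitLodResult(mid, lo, hi, n_levels, True)

    import statsmodels.api as sm

    x = np.array([math.log10(v) for v, _ in pos])
    y = np.array([1.0 if d else 0.0 for _, d in pos])
    X = sm.add_constant(x)
    model = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Probit()))
    try:
        fit = model.fit()
    except Exception:
        lo, hi = levels_sorted[0][0], levels_sorted[-1][0]
        mid = 10 ** ((math.log10(lo) + math.log10(hi)) / 2)
        return ProbitLodResult(mid, lo, hi, n_levels, True)
    a, b = fit.params
    if b <= 0:
        lo, hi = levels_sorted[0][0], levels_sorted[-1][0]
        mid = 10 ** ((math.log10(lo) + math.log10(hi)) / 2)
        return ProbitLodResult(mid, lo, hi, n_levels, True)
    z = norm.ppf(probability)
    log_lod = (z - a) / b
    grad = np.array([-1.0 / b, -(z - a) / b**2])
    var = float(grad @ fit.cov_params() @ grad)
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    return ProbitLodResult(
        lod95=10**log_lod,
        ci_low=10 ** (log_lod - half),
        ci_high=10 ** (log_lod + half),
        n_levels=n_levels,
        separation_flag=False,
        intercept=float(a),
        slope=float(b),
    )
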