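"""Concordance statistics between replicate call sets.

The central quantity is the SNV concordance rate

    Rc = Nc / mean(N1, N2)

where Nc counts positions called as an SNV in both replicates with an
identical genotype, and N1, N2 are the replicates' SNV totals.  A position
variant in only one replicate, or variant in both with differing genotypes,
is discordant.  Triplicate samples are summarised by the unweighted mean of
their three pairwise rates.

Whole-region concordance compares the per-position consensus genotype
symbols, optionally excluding positions where either call is the ambiguous
symbol ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CallSet, ReplicateSet


@dataclass(frozen=True)
class ConcordanceResult:
    """Concordant count and per-replicate totals for one pair.

    ``rate`` is Nc / mean(N1, N2).
    """

    n_concordant: int
    n_total_1: float
    n_total_2: float

    def __post_init__(self):
        if self.n_total_1 + self.n_total_2 == 0:
            raise ZeroDivisionError("both call sets empty: rate undefined")

    @property
    def n_total_mean(self) -> float:
        return 0.5 * (self.n_total_1 + self.n_total_2)

    @property
    def rate(self) -> float:
        return self.n_concordant / self.n_total_mean

    @classmethod
    def from_mean_total(cls, n_concordant: int, n_total_mean: float) -> "ConcordanceResult":
        """Build from a concordant count and an already-averaged pair total
        (the form in which published summary tables print the counts)."""
        return cls(n_concordant, n_total_mean, n_total_mean)


@dataclass(frozen=True)
class ReplicateConcordance:
    """Pairwise results for a replicate set plus their mean rate."""

    sample_id: str
    pairwise: tuple[ConcordanceResult, ...]

    @property
    def rate(self) -> float:
        return float(np.mean([r.rate for r in self.pairwise]))


def snv_concordance(a: CallSet, b: CallSet) -> ConcordanceResult:
    """SNV-call concordance between two replicates, by genotype identity."""
    if a.sample_id != b.sample_id:
        raise ValueError(f"call sets from different samples: {a.sample_id!r} vs {b.sample_id!r}")
    nc = sum(
        1 for key, va in a.variants.items()
        if (vb := b.variants.get(key)) is not None and va.genotype == vb.genotype
    )
    return ConcordanceResult(nc, len(a.variants), len(b.variants))


def replicate_concordance(reps: ReplicateSet) -> ReplicateConcordance:
    """Pairwise concordance within a replicate set; duplicates give the
    single pairwise rate, triplicates the mean of the three."""
    results = tuple(snv_concordance(a, b) for a, b in reps.pairs())
    return ReplicateConcordance(reps.sample_id, results)


def allcall_concordance(a: CallSet, b: CallSet,
                        exclude_ambiguous: bool = True) -> ConcordanceResult:
    """Concordance of consensus calls over positions present in both tables.

    With ``exclude_ambiguous`` (the headline mode) positions where either
    call is ``N`` are removed before comparison.  When ambiguous calls are
    included, ``N`` vs a base counts as discordant and ``N`` vs ``N`` as
    concordant.
    """
    for cs in (a, b):
        if cs.consensus is None:
            raise ValueError(f"replicate {cs.replicate_id!r} has no consensus table")
    joined = a.consensus[["call"]].join(
        b.consensus[["call"]], how="inner", lsuffix="_1", rsuffix="_2")
    if joined.empty:
        raise ValueError("no shared positions between consensus tables")
    if exclude_ambiguous:
        joined = joined[(joined["call_1"] != "N") & (joined["call_2"] != "N")]
        if joined.empty:
            raise ValueError("no unambiguous shared positions to compare")
    nc = int((joined["call_1"] == joined["call_2"]).sum())
    n = len(joined)
    return ConcordanceResult(nc, n, n)


def coverage_correlation(a: CallSet, b: CallSet) -> float:
    """Pearson r of consensus coverage over positions with at least one
    read in both replicates."""
    for cs in (a, b):
        if cs.consensus is None:
            raise ValueError(f"replicate {cs.replicate_id!r} has no consensus table")
    joined = a.consensus[["coverage"]].join(
        b.consensus[["coverage"]], how="inner", lsuffix="_1", rsuffix="_2")
    joined = joined[(joined["coverage_1"] >= 1) & (joined["coverage_2"] >= 1)]
    if len(joined) < 3:
        raise ValueError("fewer than 3 positions covered in both replicates")
    r, _ = stats.pearsonr(joined["coverage_1"], joined["coverage_2"])
    return float(r)


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2), with sample
    (n-1) variances.  Measures agreement with the identity line: attenuated
    relative to Pearson r by location or scale shifts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-d vectors required")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    sxy = np.cov(x, y, ddof=1)[0, 1]
    return float(2 * sxy / (x.var(ddof=1) + y.var(ddof=1) + (x.mean() - y.mean()) ** 2))


@dataclass(frozen=True)
class MetricCorrelation:
    metric_name: str
    spearman_rho: float
    lin_ccc: float


def metric_correlations(metrics_a: Sequence[float], metrics_b: Sequence[float],
                        metric_name: str = "") -> MetricCorrelation:
    """Spearman rho and Lin's CCC between paired per-sample sequencing
    metrics (e.g. total reads, mean coverage per replicate)."""
    x = np.asarray(metrics_a, dtype=float)
    y = np.asarray(metrics_b, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("paired vectors of length >= 3 required")
    rho, _ = stats.spearmanr(x, y)
    return MetricCorrelation(metric_name, float(rho), lin_ccc(x, y))


def rate_percent(result: ConcordanceResult, decimals: int = 1) -> float:
    """Rate as a percentage, rounded half-up to ``decimals`` places (the
    convention used when printing concordance tables)."""
    from decimal import ROUND_HALF_UP, Decimal
    pct = Decimal(int(result.n_concordant)) / Decimal(str(float(result.n_total_mean))) * 100
    return float(pct.quantize(Decimal("1." + "0" * decimals), rounding=ROUND_HALF_UP))


def concordance_table(results: dict[str, ReplicateConcordance]) -> pd.DataFrame:
    """Tidy per-pair concordance table: sample_id, pair, n_concordant,
    n1, n2, rate."""
    rows = []
    for sample_id, rc in results.items():
        for i, r in enumerate(rc.pairwise, start=1):
            rows.append({
                "sample_id": sample_id, "pair": i,
                "n_concordant": r.n_concordant,
                "n1": r.n_total_1, "n2": r.n_total_2,
                "rate": r.rate,
            })
    return pd.DataFrame(rows)
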