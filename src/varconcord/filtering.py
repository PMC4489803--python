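"""Threshold filters on variant calls and their effect on concordance.

Two preset criteria families mirror how thresholds are derived from a
replicate study: *pooled* criteria take the mean factor values of the
reproduced SNV group (the published preset is min-coverage 78, min-VAC 45,
min-VAF 0.6, min-VAQ 22), while *categorized* criteria come from reading
the stratified concordance curves (coverage 20, VAC 20, VAF 0.3, VAQ 20 —
strictly weaker in every field).  Applying a filter to both replicates and
recomputing Rc quantifies how much of the discordance lives in the
low-evidence calls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .concordance import snv_concordance
from .io import CallSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterCriteria:
    """Lower-bound thresholds on call evidence (upper bound on p-value)."""

    min_coverage: float = 0.0
    min_vac: float = 0.0
    min_vaf: float = 0.0
    min_vaq: float = 0.0
    max_pvalue: Optional[float] = None

    def __post_init__(self):
        for name in ("min_coverage", "min_vac", "min_vaf", "min_vaq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_vaf > 1:
            raise ValueError("min_vaf must be <= 1")

    def is_identity(self) -> bool:
        return (self.min_coverage == self.min_vac == self.min_vaf == self.min_vaq == 0
                and self.max_pvalue is None)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_mapping(cls, d) -> "FilterCriteria":
        return cls(**{k: d[k] for k in
                      ("min_coverage", "min_vac", "min_vaf", "min_vaq", "max_pvalue")
                      if k in d})


def pooled_criteria(table: pd.DataFrame) -> FilterCriteria:
    """Derive thresholds from the pooled reproduced (status=1) group:
    the group's mean coverage/VAC/VAQ rounded to integers and mean VAF
    rounded to one decimal."""
    rep = table[table["status"] == 1]
    if rep.empty:
        raise ValueError("reproduced group is empty")
    return FilterCriteria(
        min_coverage=float(round(rep["coverage"].mean())),
        min_vac=float(round(rep["vac"].mean())),
        min_vaf=round(float(rep["vaf"].mean()), 1),
        min_vaq=float(round(rep["vaq"].mean())),
    )


def pooled_criteria_preset() -> FilterCriteria:
    """The published pooled-group preset: coverage 78, VAC 45, VAF 0.6,
    VAQ 22."""
    return FilterCriteria(min_coverage=78, min_vac=45, min_vaf=0.6, min_vaq=22)


def categorized_criteria() -> FilterCriteria:
    """The categorized-analysis preset: coverage 20, VAC 20, VAF 0.3,
    VAQ 20 — strictly weaker than the pooled preset in every field."""
    return FilterCriteria(min_coverage=20, min_vac=20, min_vaf=0.3, min_vaq=20)


_RULES = (
    ("min_coverage", "coverage"),
    ("min_vac", "vac"),
    ("min_vaf", "vaf"),
    ("min_vaq", "vaq"),
)


def apply_filter(cs: CallSet, c: FilterCriteria,
                 on_missing: str = "drop") -> CallSet:
    """Keep variants meeting every threshold; idempotent.

    A variant missing a thresholded field is dropped and logged by default
    (``on_missing``: drop | keep | error).  Per-rule removal counts are
    logged (a variant may fail several rules; each is counted).
    """
    if on_missing not in ("drop", "keep", "error"):
        raise ValueError("on_missing must be drop/keep/error")
    kept: dict = {}
    fail_counts = {rule: 0 for rule, _ in _RULES}
    fail_counts["max_pvalue"] = 0
    fail_counts["missing"] = 0
    for key, v in cs.variants.items():
        ok = True
        for rule, fieldname in _RULES:
            thr = getattr(c, rule)
            val = getattr(v, fieldname)
            if val is None:
                if thr > 0:
                    if on_missing == "error":
                        raise ValueError(f"variant {key} missing {fieldname}")
                    if on_missing == "drop":
                        fail_counts["missing"] += 1
                        ok = False
                continue
            if val < thr:
                fail_counts[rule] += 1
                ok = False
        if c.max_pvalue is not None:
            if v.pvalue is None:
                if on_missing == "error":
                    raise ValueError(f"variant {key} missing pvalue")
                if on_missing == "drop":
                    fail_counts["missing"] += 1
                    ok = False
            elif v.pvalue > c.max_pvalue:
                fail_counts["max_pvalue"] += 1
                ok = False
        if ok:
            kept[key] = v
    removed = len(cs.variants) - len(kept)
    logger.info("apply_filter(%s/%s): removed %d of %d (%s)",
                cs.sample_id, cs.replicate_id, removed, len(cs.variants),
                ", ".join(f"{k}={n}" for k, n in fail_counts.items() if n))
    return CallSet(sample_id=cs.sample_id, replicate_id=cs.replicate_id,
                   variants=kept, consensus=cs.consensus)


def coverage_filter_pair(a: CallSet, b: CallSet,
                         min_cov: float = 20) -> tuple[CallSet, CallSet]:
    """Remove SNV positions whose coverage is below ``min_cov`` in either
    or both replicates (coverage from each replicate's own record, else
    its consensus table), from both call sets."""
    keys = set(a.variants) | set(b.variants)
    keep = set()
    for key in keys:
        ca = a.factor_at(key, "coverage")
        cb = b.factor_at(key, "coverage")
        if ca is not None and cb is not None and ca >= min_cov and cb >= min_cov:
            keep.add(key)
    return a.restrict_to(keep), b.restrict_to(keep)


@dataclass(frozen=True)
class FilterEffect:
    """Before/after concordance across replicate pairs."""

    rates_before: tuple[float, ...]
    rates_after: tuple[float, ...]
    excluded_pairs: int
    paired_t_pvalue: float  # NaN when the filter changed nothing

    @property
    def mean_before(self) -> float:
        return float(np.mean(self.rates_before))

    @property
    def mean_after(self) -> float:
        return float(np.mean(self.rates_after))

    @property
    def sd_before(self) -> float:
        return float(np.std(self.rates_before, ddof=1))

    @property
    def sd_after(self) -> float:
        return float(np.std(self.rates_after, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"condition": "unfiltered", "mean_rate": self.mean_before,
             "sd": self.sd_before, "p_vs_baseline": np.nan},
            {"condition": "filtered", "mean_rate": self.mean_after,
             "sd": self.sd_after, "p_vs_baseline": self.paired_t_pvalue},
        ])


def filter_effect(pairs: Sequence[tuple[CallSet, CallSet]],
                  c: FilterCriteria) -> FilterEffect:
    """Per-pair Rc before and after filtering both replicates, with a
    two-sided paired t-test on the per-pair differences.  Pairs emptied by
    the filter are excluded (with a warning in the log)."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 replicate pairs")
    before, after = [], []
    excluded = 0
    for a, b in pairs:
        r0 = snv_concordance(a, b)
        fa, fb = apply_filter(a, c), apply_filter(b, c)
        if len(fa.variants) + len(fb.variants) == 0:
            logger.warning("pair %s emptied by filter; excluded", a.sample_id)
            excluded += 1
            continue
        before.append(r0.rate)
        after.append(snv_concordance(fa, fb).rate)
    if len(before) < 2:
        raise ValueError("fewer than 2 pairs survive filtering")
    diffs = np.subtract(after, before)
    if np.allclose(diffs, 0):
        p = float("nan")  # no difference to test
    else:
        _, p = stats.ttest_rel(after, before)
        p = float(p)
    return FilterEffect(tuple(before), tuple(after), excluded, p)
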