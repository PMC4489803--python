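"""Factor categorisation and concordance stratified by factor category.

Continuous factors (coverage, VAC, VAF, VAQ, SNV-call p-value, GC content)
are cut into ordered bins three ways: fixed empirical depth bins, Sturges'
histogram rule over the pooled values (optionally log10-transformed), or a
natural categorical scheme (substitution type, genome annotation).  Sparse
bins at the two tails are merged inward.  Concordance within a category
uses the same-bin pairing rule: a position enters a factor's analysis only
if its factor value falls in the same bin in both replicates; positions in
different bins are disregarded for that factor.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ANNOTATION_CLASSES, BASES, CallSet

TRANSITIONS = frozenset({"A>G", "G>A", "C>T", "T>C"})

#: Factors whose per-position value is categorical rather than numeric.
CATEGORICAL_FACTORS = ("substitution_type", "annotation")


@dataclass(frozen=True)
class BinScheme:
    """Ordered categories for one factor.

    Numeric schemes hold strictly increasing ``edges`` on the transformed
    scale (left-closed, right-open; the final bin is closed above, and an
    infinite last edge makes it unbounded).  Categorical schemes hold an
    ordered label list instead.
    """

    factor_name: str
    edges: Optional[tuple[float, ...]] = None
    labels: tuple[str, ...] = ()
    transform: str = "none"  # none | log10
    categories: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        if (self.edges is None) == (self.categories is None):
            raise ValueError("exactly one of edges/categories must be given")
        if self.edges is not None:
            e = np.asarray(self.edges, dtype=float)
            if len(e) < 2 or not np.all(np.diff(e) > 0):
                raise ValueError("edges must be strictly increasing, length >= 2")
            if self.labels and len(self.labels) != len(e) - 1:
                raise ValueError("labels count must equal bin count")
        else:
            if self.labels and len(self.labels) != len(self.categories):
                raise ValueError("labels count must equal category count")

    @property
    def n_bins(self) -> int:
        return len(self.categories) if self.categories is not None else len(self.edges) - 1

    def bin_labels(self) -> tuple[str, ...]:
        if self.labels:
            return self.labels
        if self.categories is not None:
            return self.categories
        out = []
        for lo, hi in zip(self.edges[:-1], self.edges[1:]):
            out.append(f"[{lo:g},{hi:g})" if np.isfinite(hi) else f">={lo:g}")
        return tuple(out)

    def assign(self, values) -> np.ndarray:
        """Bin index per value; -1 for out-of-range / unknown.

        Numeric values are transformed first; each in-range value maps to
        exactly one bin (partition property).
        """
        if self.categories is not None:
            lookup = {c: i for i, c in enumerate(self.categories)}
            return np.array([lookup.get(v, -1) for v in values], dtype=int)
        x = np.asarray(values, dtype=float)
        if self.transform == "log10":
            with np.errstate(divide="ignore", invalid="ignore"):
                x = np.log10(x)
        edges = np.asarray(self.edges, dtype=float)
        idx = np.digitize(x, edges, right=False) - 1
        # final bin is closed above
        idx[np.isclose(x, edges[-1])] = len(edges) - 2
        idx[(x < edges[0]) | (x > edges[-1]) | np.isnan(x)] = -1
        return idx

    def to_json(self) -> str:
        return json.dumps({
            "factor_name": self.factor_name,
            "edges": list(self.edges) if self.edges is not None else None,
            "categories": list(self.categories) if self.categories is not None else None,
            "labels": list(self.bin_labels()),
            "transform": self.transform,
        })

    @classmethod
    def from_json(cls, s: str) -> "BinScheme":
        d = json.loads(s)
        return cls(
            factor_name=d["factor_name"],
            edges=None if d["edges"] is None else tuple(d["edges"]),
            categories=None if d["categories"] is None else tuple(d["categories"]),
            labels=tuple(d["labels"]),
            transform=d["transform"],
        )


def empirical_coverage_bins() -> BinScheme:
    """The fixed five-category depth scheme: 1-4x, 5-19x, 20-79x, 80-199x,
    >=200x."""
    return BinScheme(
        factor_name="coverage",
        edges=(1.0, 5.0, 20.0, 80.0, 200.0, math.inf),
        labels=("1-4x", "5-19x", "20-79x", "80-199x", "≥200x"),
    )


def gc_bins(split: float = 0.5) -> BinScheme:
    """Two-class GC-content scheme split at 50% (the empirical GC
    distribution of exon-capture targets is loosely bimodal around 50%)."""
    return BinScheme(factor_name="gc_content", edges=(0.0, split, 1.0),
                     labels=(f"<{split:.0%}", f"≥{split:.0%}"))


def sturges_bins(values, factor_name: str = "", transform: str = "none") -> BinScheme:
    """Equal-width bins over the observed range with Sturges' bin count
    k = ceil(log2(n) + 1), optionally on the log10 scale.

    The classical histogram implementation snaps edges to round numbers;
    here edges span [min, max] exactly, so bin counts can differ by one or
    two from a snapped histogram of the same data.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no values to bin")
    if transform == "log10":
        if np.any(x <= 0):
            raise ValueError("log10 transform requires positive values")
        x = np.log10(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        warnings.warn(f"constant factor values for {factor_name!r}: single bin")
        return BinScheme(factor_name=factor_name, edges=(lo, np.nextafter(hi, math.inf)),
                         transform=transform)
    k = math.ceil(math.log2(x.size) + 1)
    edges = tuple(np.linspace(lo, hi, k + 1))
    return BinScheme(factor_name=factor_name, edges=edges, transform=transform)


def merge_tail_bins(scheme: BinScheme, counts: Sequence[int],
                    min_count: Optional[int] = None) -> BinScheme:
    """Merge sparse tail bins inward.

    Leftmost bins with fewer than ``min_count`` positions are folded into
    their right neighbour, repeatedly, and likewise rightmost bins into
    their left neighbour; interior bins are untouched.  Default
    ``min_count`` is max(30, 0.1% of the total count).  The result is a
    coarsening: every value keeps its relative order and no value changes
    bins except by absorption.
    """
    if scheme.edges is None:
        raise ValueError("tail merging applies to numeric schemes only")
    counts = list(counts)
    if len(counts) != scheme.n_bins:
        raise ValueError("counts must align with scheme bins")
    if min_count is None:
        min_count = max(30, math.ceil(0.001 * sum(counts)))
    edges = list(scheme.edges)
    # interior edge i separates bin i-1 from bin i
    while len(counts) > 1 and counts[0] < min_count:
        counts[1] += counts[0]
        del counts[0], edges[1]
    while len(counts) > 1 and counts[-1] < min_count:
        counts[-2] += counts[-1]
        del counts[-1], edges[-2]
    if len(counts) == 1 and counts[0] < min_count:
        warnings.warn(f"all bins below min_count={min_count}; single-bin scheme")
    return BinScheme(factor_name=scheme.factor_name, edges=tuple(edges),
                     transform=scheme.transform)


def categorical_scheme(factor_name: str) -> BinScheme:
    """Natural categories: the 12 ordered ref>alt substitution types, or
    the 10 genome-annotation classes."""
    if factor_name == "substitution_type":
        cats = tuple(f"{r}>{a}" for r in BASES for a in BASES if a != r)
        return BinScheme(factor_name=factor_name, categories=cats)
    if factor_name == "annotation":
        return BinScheme(factor_name=factor_name, categories=ANNOTATION_CLASSES)
    raise ValueError(f"no natural categories for {factor_name!r}")


def is_transition(substitution: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine substitutions."""
    return substitution in TRANSITIONS


@dataclass(frozen=True)
class BinResult:
    label: str
    n_positions: int
    n_concordant: int
    n1: int
    n2: int

    @property
    def rate(self) -> Optional[float]:
        tot = 0.5 * (self.n1 + self.n2)
        return None if tot == 0 else self.n_concordant / tot


@dataclass(frozen=True)
class StratifiedConcordance:
    """Per-bin concordance for one factor and one replicate pair."""

    factor_name: str
    bins: tuple[BinResult, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "factor": self.factor_name, "bin": b.label,
            "n_positions": b.n_positions, "n_concordant": b.n_concordant,
            "n1": b.n1, "n2": b.n2, "rate": b.rate,
        } for b in self.bins])


def _factor_value(cs: CallSet, key, factor_name: str):
    """Per-replicate factor value at a position.

    Numeric factors fall back to the consensus-table record when the
    position is not an SNV call in this replicate; categorical factors
    exist only on variant records.
    """
    v = cs.variants.get(key)
    if factor_name == "substitution_type":
        return v.substitution if v is not None else None
    if factor_name == "annotation":
        return v.annotation if v is not None else None
    return cs.factor_at(key, factor_name)


def concordance_by_factor(a: CallSet, b: CallSet, factor_name: str,
                          scheme: BinScheme, value_fn=None) -> StratifiedConcordance:
    """Concordance within each factor category under the same-bin rule.

    For each position called as an SNV in at least one replicate, the
    factor value is looked up in each replicate (its own variant record,
    else its consensus record).  The position contributes to a bin only
    when both replicates' values fall in that bin; otherwise it is dropped
    from this factor's analysis.  For categorical factors a replicate with
    no variant call at the position carries no category, and the calling
    replicate's category is used for both (the same-bin rule is then
    trivially met unless both replicates call different categories).
    Within a bin the genotype rule applies as in the unstratified rate.

    ``value_fn`` supplies a position-level factor value (e.g. the GC
    fraction of the window containing the position, via
    ``lambda key: track.gc_at(*key)``); it is shared by both replicates,
    so the same-bin rule is then trivially satisfied.
    """
    if scheme.factor_name and scheme.factor_name != factor_name:
        raise ValueError(f"scheme is for {scheme.factor_name!r}, not {factor_name!r}")
    keys = sorted(set(a.variants) | set(b.variants))
    categorical = scheme.categories is not None
    per_bin = {i: {"n_pos": 0, "nc": 0, "n1": 0, "n2": 0} for i in range(scheme.n_bins)}
    for key in keys:
        if value_fn is not None:
            fa = fb = value_fn(key)
        else:
            fa = _factor_value(a, key, factor_name)
            fb = _factor_value(b, key, factor_name)
        if categorical:
            fa = fa if fa is not None else fb
            fb = fb if fb is not None else fa
        if fa is None or fb is None:
            continue
        ia, ib = scheme.assign([fa, fb])
        if ia != ib or ia < 0:
            continue  # different categories in the pair: disregarded
        rec = per_bin[int(ia)]
        rec["n_pos"] += 1
        va, vb = a.variants.get(key), b.variants.get(key)
        if va is not None:
            rec["n1"] += 1
        if vb is not None:
            rec["n2"] += 1
        if va is not None and vb is not None and va.genotype == vb.genotype:
            rec["nc"] += 1
    labels = scheme.bin_labels()
    return StratifiedConcordance(factor_name, tuple(
        BinResult(labels[i], per_bin[i]["n_pos"], per_bin[i]["nc"],
                  per_bin[i]["n1"], per_bin[i]["n2"])
        for i in range(scheme.n_bins)
    ))


def stratified_rates_over_pairs(pairs, factor_name: str,
                                scheme: BinScheme, value_fn=None) -> pd.DataFrame:
    """Long table of per-pair per-bin concordance rates across many
    replicate pairs: columns pair_id, bin, n_positions, rate."""
    rows = []
    for pair_id, (a, b) in enumerate(pairs):
        strat = concordance_by_factor(a, b, factor_name, scheme, value_fn=value_fn)
        for bres in strat.bins:
            if bres.rate is not None:
                rows.append({"pair_id": pair_id, "bin": bres.label,
                             "n_positions": bres.n_positions, "rate": bres.rate})
    return pd.DataFrame(rows)
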