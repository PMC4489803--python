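"""End-to-end report assembly: pooling, concordance, stratification,
association and filtering over a collection of replicate sets.

A run is driven by a :class:`RunConfig` (typically loaded from YAML) that
either simulates replicate sets deterministically from a seed or loads
them from a manifest of consensus-table files.  Each stage writes one
machine-readable output under the run directory:

======================  =====================================================
concordance.tsv         per-pair SNV and whole-region concordance
stratified.tsv          per-factor per-bin concordance rates
association.json        MI / AIC / lasso-entry / R^2 per factor
filtering.tsv           mean rate before/after the configured filter
run.json                tool version, seed, config hash, output inventory
======================  =====================================================
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import pool_status, summarize_associations
from .binning import (
    BinScheme,
    empirical_coverage_bins,
    merge_tail_bins,
    stratified_rates_over_pairs,
    sturges_bins,
)
from .concordance import allcall_concordance, replicate_concordance
from .filtering import (
    FilterCriteria,
    categorized_criteria,
    filter_effect,
    pooled_criteria,
    pooled_criteria_preset,
)
from .io import CallSet, ReplicateSet, read_consensus_table
from .simulate import SimulationConfig, simulate_replicate_set

logger = logging.getLogger(__name__)

STAGES = ("concord", "stratify", "associate", "filter")


@dataclass
class RunConfig:
    """Validated run configuration.

    Exactly one of ``simulate`` / ``samples`` provides the input:
    ``simulate`` is a mapping of overrides for :class:`SimulationConfig`
    plus ``n_samples``; ``samples`` maps sample ids to lists of 2-3
    consensus-table paths (one per replicate).
    """

    out_dir: Path
    seed: int = 0
    simulate: Optional[dict] = None
    samples: Optional[dict] = None
    filter_preset: str = "categorized"   # categorized | pooled | pooled_preset
    filter_thresholds: Optional[dict] = None
    bin_min_count: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if (self.simulate is None) == (self.samples is None):
            raise ValueError("exactly one of simulate/samples must be configured")
        if self.samples is not None:
            for sample_id, paths in self.samples.items():
                if not 2 <= len(paths) <= 3:
                    raise ValueError(f"sample {sample_id}: need 2-3 replicates")
                for p in paths:
                    if not Path(p).exists():
                        raise FileNotFoundError(f"sample {sample_id}: missing {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in dataclasses.asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def criteria(self, status_table: Optional[pd.DataFrame] = None) -> FilterCriteria:
        if self.filter_thresholds is not None:
            return FilterCriteria.from_mapping(self.filter_thresholds)
        if self.filter_preset == "categorized":
            return categorized_criteria()
        if self.filter_preset == "pooled_preset":
            return pooled_criteria_preset()
        if self.filter_preset == "pooled":
            if status_table is None:
                raise ValueError("pooled criteria need the pooled status table")
            return pooled_criteria(status_table)
        raise ValueError(f"unknown filter preset {self.filter_preset!r}")


def load_replicate_sets(config: RunConfig) -> list[ReplicateSet]:
    """Materialise the run's replicate sets (simulate or read manifest)."""
    if config.simulate is not None:
        opts = dict(config.simulate)
        n_samples = int(opts.pop("n_samples", 2))
        sets = []
        for i in range(n_samples):
            sim = SimulationConfig(seed=config.seed + i,
                                   sample_id=f"S{i + 1:02d}", **opts)
            reps, _, _ = simulate_replicate_set(sim)
            sets.append(reps)
        return sets
    sets = []
    for sample_id, paths in config.samples.items():
        reps = [read_consensus_table(p, sample_id=sample_id,
                                     replicate_id=f"R{j + 1}")
                for j, p in enumerate(paths)]
        sets.append(ReplicateSet(sample_id=sample_id, replicates=reps))
    return sets


def all_pairs(sets: Sequence[ReplicateSet]) -> list[tuple[CallSet, CallSet]]:
    return [pair for reps in sets for pair in reps.pairs()]


def build_schemes(status_table: pd.DataFrame,
                  min_count: Optional[int] = None) -> dict[str, BinScheme]:
    """Bin schemes per factor from the pooled SNV-position values: the
    fixed empirical depth bins for coverage, Sturges bins (log10 for VAC)
    with tail merging for the rest."""
    schemes: dict[str, BinScheme] = {"coverage": empirical_coverage_bins()}
    for f, transform in (("vac", "log10"), ("vaf", "none"),
                         ("vaq", "none"), ("pvalue", "none")):
        vals = status_table[f].dropna().to_numpy()
        if transform == "log10":
            vals = vals[vals > 0]
        scheme = sturges_bins(vals, factor_name=f, transform=transform)
        counts = np.bincount(scheme.assign(vals)[scheme.assign(vals) >= 0],
                             minlength=scheme.n_bins)
        schemes[f] = merge_tail_bins(scheme, counts, min_count=min_count)
    return schemes


def stage_concord(sets: Sequence[ReplicateSet], out: Path) -> pd.DataFrame:
    rows = []
    for reps in sets:
        rc = replicate_concordance(reps)
        for i, (res, (a, b)) in enumerate(zip(rc.pairwise, reps.pairs()), start=1):
            row = {"sample_id": reps.sample_id, "pair": i,
                   "n_concordant": res.n_concordant,
                   "n1": res.n_total_1, "n2": res.n_total_2,
                   "snv_rate": res.rate}
            if a.consensus is not None and b.consensus is not None:
                ac = allcall_concordance(a, b, exclude_ambiguous=True)
                row["allcall_rate"] = ac.rate
                row["allcall_concordant"] = ac.n_concordant
                row["allcall_total"] = ac.n_total_mean
            rows.append(row)
        rows.append({"sample_id": reps.sample_id, "pair": "mean",
                     "snv_rate": rc.rate})
    df = pd.DataFrame(rows)
    df.to_csv(out, sep="\t", index=False)
    return df


def stage_stratify(sets: Sequence[ReplicateSet],
                   schemes: dict[str, BinScheme], out: Path
                   ) -> dict[str, pd.DataFrame]:
    pairs = all_pairs(sets)
    tables = {}
    frames = []
    for f, scheme in schemes.items():
        t = stratified_rates_over_pairs(pairs, f, scheme)
        tables[f] = t
        if not t.empty:
            t = t.assign(factor=f)
            frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(out, sep="\t", index=False)
    return tables


def stage_associate(status_table: pd.DataFrame, schemes: dict[str, BinScheme],
                    stratified: dict[str, pd.DataFrame], out: Path) -> dict:
    strat_ok = {}
    for f, t in stratified.items():
        if not t.empty and t["bin"].nunique() >= 2:
            strat_ok[f] = t
    summary = summarize_associations(status_table, schemes, strat_ok)
    payload = json.loads(summary.to_json())
    out.write_text(json.dumps(payload, indent=2))
    return payload


def stage_filter(sets: Sequence[ReplicateSet], criteria: FilterCriteria,
                 out: Path):
    eff = filter_effect(all_pairs(sets), criteria)
    df = eff.to_frame()
    df.insert(0, "criteria", criteria.to_json())
    df.to_csv(out, sep="\t", index=False)
    return eff


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the report bundle.

    Any stage failure aborts with the stage name; outputs of earlier
    stages are left in place.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "load"
    try:
        sets = load_replicate_sets(config)
        stage = "concord"
        outputs["concordance"] = out / "concordance.tsv"
        stage_concord(sets, outputs["concordance"])

        stage = "pool"
        status = pool_status(all_pairs(sets))
        schemes = build_schemes(status, min_count=config.bin_min_count)
        (out / "bin_schemes.json").write_text(json.dumps(
            {f: json.loads(s.to_json()) for f, s in schemes.items()}, indent=2))
        outputs["bin_schemes"] = out / "bin_schemes.json"

        stage = "stratify"
        outputs["stratified"] = out / "stratified.tsv"
        stratified = stage_stratify(sets, schemes, outputs["stratified"])

        stage = "associate"
        outputs["association"] = out / "association.json"
        stage_associate(status, schemes, stratified, outputs["association"])

        stage = "filter"
        outputs["filtering"] = out / "filtering.tsv"
        stage_filter(sets, config.criteria(status), outputs["filtering"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    meta = {
        "tool": "varconcord",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    (out / "run.json").write_text(json.dumps(meta, indent=2))
    outputs["run"] = out / "run.json"
    return outputs
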