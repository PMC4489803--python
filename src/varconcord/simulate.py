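"""Synthetic replicate call sets with ground truth.

The generator emulates the statistical structure of replicate targeted
sequencing of the same genomic DNA, at a scaled-down target size:

* true variants are placed once and shared by all replicates, with a
  variant-allele-frequency mixture peaking near 1 (homozygous alternate)
  with a much lower secondary peak near 0.5 (heterozygous) and a small
  low-frequency tail;
* coverage is negative-binomial per position, with lower mean depth in
  GC-rich windows (the capture chemistry penalty; roughly a third of the
  GC-poor depth), higher mean depth in exons than introns, and a
  per-batch multiplicative total-read factor;
* each replicate re-samples its own coverage and variant allele count
  (VAC ~ Binomial(coverage, true VAF)); a true variant is emitted only if
  its sampled evidence passes an implicit detection rule (VAC >= 2 and a
  binomial test against the background error rate), so replicate dropout
  — and hence discordance — is causally driven by coverage and VAC;
* independent low-VAC false calls are added per replicate and never
  shared;
* SNV-call p-values put a point mass at 0 for well-supported calls (91%
  of calls in the regime emulated) and are otherwise uniform;
* variant allele quality sits on a 0-35 scale, stochastically higher for
  true calls than false ones.

Every draw comes from one seeded generator, so identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    BASES,
    CallSet,
    GCTrack,
    ReplicateSet,
    VariantCall,
    call_from_genotype,
    write_consensus_table,
    write_vcf,
)


@dataclass(frozen=True)
class VafMixture:
    """Three-component true-VAF mixture: homozygous-like peak near 1,
    heterozygous peak near 0.5, low-frequency tail."""

    weights: tuple[float, float, float] = (0.60, 0.25, 0.15)
    hom_beta: tuple[float, float] = (40.0, 2.0)    # mode ~0.97
    het_beta: tuple[float, float] = (60.0, 60.0)   # tight around 0.5
    tail_beta: tuple[float, float] = (2.0, 8.0)    # low-frequency tail

    def __post_init__(self):
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (vaf, component) with component 0=hom, 1=het, 2=tail."""
        comp = rng.choice(3, size=n, p=self.weights)
        params = [self.hom_beta, self.het_beta, self.tail_beta]
        vaf = np.empty(n)
        for k, (a, b) in enumerate(params):
            m = comp == k
            vaf[m] = rng.beta(a, b, size=int(m.sum()))
        return vaf, comp


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated replicate set.

    Defaults describe a 50 kb slice of an exon-capture target sequenced to
    a mean depth of 80x, with 1000 shared true variants and independent
    per-replicate false calls amounting to ~30% of the true count.
    """

    seed: int = 0
    sample_id: str = "sim"
    n_target_bp: int = 50_000
    n_true_variants: int = 1000
    true_vaf_mixture: VafMixture = field(default_factory=VafMixture)
    error_rate_per_replicate: float = 0.006   # expected false SNVs per bp
    coverage_mean: float = 80.0
    coverage_dispersion: float = 5.0          # per-replicate negative-binomial size r
    capture_shape: float = 3.0                # shared per-position capture-efficiency Gamma shape
    vaq_concentration: float = 60.0           # per-replicate Beta concentration around the
                                              # shared per-position quality propensity
    gc_effect: float = 0.34                   # GC-rich / GC-poor mean depth ratio
    gc_window_bp: int = 500
    exon_coverage_multiplier: float = 1.5     # exon vs intron capture efficiency
    pvalue_zero_mass: float = 0.91
    pvalue_highvac_threshold: int = 10        # calls with VAC >= this get the 0-mass
    n_replicates: int = 2
    batch_scale: float = 1.0
    batch_id: str = "batch1"
    detect_min_vac: int = 2
    detect_pvalue: float = 1e-4               # binomial test vs background
    background_error: float = 0.05            # per-read background mismatch rate
    ambiguous_call_rate: float = 0.02         # consensus 'N' probability
    dropout: bool = True                      # detection rule on true variants
    chrom: str = "kin1"

    def __post_init__(self):
        if not 2 <= self.n_replicates <= 3:
            raise ValueError("n_replicates must be 2 or 3")
        if not 0 <= self.pvalue_zero_mass <= 1:
            raise ValueError("pvalue_zero_mass must be in [0,1]")
        if self.error_rate_per_replicate < 0 or self.coverage_mean <= 0:
            raise ValueError("rates must be non-negative, coverage_mean positive")
        expected_calls = (self.n_true_variants
                         + self.error_rate_per_replicate * self.n_target_bp)
        if expected_calls <= 0:
            raise ValueError("degenerate config: expected call count is 0")


@dataclass
class GroundTruth:
    """Truth table for the simulated target.

    ``variants`` has one row per planted true variant (pos, ref,
    variant_allele, true_vaf, true_genotype, component); every emitted
    true call appears here and no false call does.
    """

    chrom: str
    variants: pd.DataFrame

    def is_true_variant(self, key: tuple[str, int]) -> bool:
        return key[0] == self.chrom and key[1] in set(self.variants["pos"])


def _annotation_blocks(n_bp: int) -> np.ndarray:
    """Cycle exon/intron/UTR blocks over the target; index by pos-1."""
    pattern = [("exonic", 200), ("intronic", 600), ("UTR3", 100),
               ("exonic", 200), ("intronic", 600), ("UTR5", 100)]
    ann = np.empty(n_bp, dtype=object)
    i = 0
    while i < n_bp:
        for label, width in pattern:
            ann[i:i + width] = label
            i += width
            if i >= n_bp:
                break
    return ann


def _gc_windows(rng: np.random.Generator, n_bp: int, window: int) -> pd.DataFrame:
    """Loosely bimodal GC fractions split at 50%, one value per window."""
    n_win = int(np.ceil(n_bp / window))
    high = rng.random(n_win) < 0.45
    gc = np.where(high,
                  rng.normal(0.62, 0.05, n_win),
                  rng.normal(0.40, 0.05, n_win))
    gc = np.clip(gc, 0.2, 0.8)
    starts = np.arange(n_win) * window
    return pd.DataFrame({"chrom": "", "start": starts,
                         "end": np.minimum(starts + window, n_bp),
                         "gc_fraction": gc})


def simulate_replicate_set(config: SimulationConfig
                           ) -> tuple[ReplicateSet, GroundTruth, GCTrack]:
    """Generate a replicate set, its ground truth and its GC track."""
    rng = np.random.default_rng(config.seed)
    n_bp = config.n_target_bp
    chrom = config.chrom

    ref = rng.choice(np.array(BASES), size=n_bp)
    annotation = _annotation_blocks(n_bp)
    gc_df = _gc_windows(rng, n_bp, config.gc_window_bp)
    gc_df["chrom"] = chrom
    gc_per_pos = np.repeat(gc_df["gc_fraction"].to_numpy(),
                           config.gc_window_bp)[:n_bp]

    # per-position mean depth: GC penalty x exon capture boost x batch scale
    # x a shared capture-efficiency propensity (probe affinity, mappability)
    # that replicates of the same library design have in common
    mu = np.full(n_bp, config.coverage_mean)
    mu[gc_per_pos > 0.5] *= config.gc_effect
    mu[annotation == "exonic"] *= config.exon_coverage_multiplier
    mu *= config.batch_scale
    mu *= rng.gamma(config.capture_shape, 1.0 / config.capture_shape, size=n_bp)
    mu = np.maximum(mu, 1e-6)

    # shared per-position quality propensities (sequence context); each
    # replicate's VAQ is a noisy draw around them
    q_true_prop = rng.beta(6.0, 2.5, size=config.n_true_variants)
    q_bg_prop = rng.beta(2.0, 5.0, size=n_bp)

    # plant true variants
    true_pos = np.sort(rng.choice(n_bp, size=config.n_true_variants,
                                  replace=False)) + 1  # 1-based
    true_vaf, comp = config.true_vaf_mixture.sample(rng, config.n_true_variants)
    alt_offset = rng.integers(1, 4, size=config.n_true_variants)
    base_idx = {b: i for i, b in enumerate(BASES)}
    true_ref = ref[true_pos - 1]
    true_alt = np.array([BASES[(base_idx[r] + o) % 4]
                         for r, o in zip(true_ref, alt_offset)])
    # homozygous-like component -> alt/alt, others -> ref/alt
    true_gt = [
        (a, a) if c == 0 else tuple(sorted((r, a)))
        for r, a, c in zip(true_ref, true_alt, comp)
    ]
    truth = GroundTruth(chrom, pd.DataFrame({
        "pos": true_pos, "ref": true_ref, "variant_allele": true_alt,
        "true_vaf": true_vaf, "component": comp,
        "true_genotype": ["/".join(g) for g in true_gt],
    }))
    true_pos_set = set(int(p) for p in true_pos)

    r_disp = config.coverage_dispersion
    replicates = []
    for rep_i in range(config.n_replicates):
        rep_id = f"R{rep_i + 1}"
        p_nb = r_disp / (r_disp + mu)
        coverage = rng.negative_binomial(r_disp, p_nb)

        # background consensus factor values (non-variant positions)
        bg_vac = rng.binomial(coverage, config.background_error)
        with np.errstate(divide="ignore", invalid="ignore"):
            bg_vaf = np.where(coverage > 0, bg_vac / np.maximum(coverage, 1), 0.0)
        conc = config.vaq_concentration
        bg_vaq = 35.0 * rng.beta(conc * q_bg_prop, conc * (1 - q_bg_prop))
        bg_pval = rng.uniform(np.nextafter(0, 1), 1.0, size=n_bp)

        call = ref.astype(object).copy()
        vac_col = bg_vac.astype(float)
        vaf_col = bg_vaf.astype(float)
        vaq_col = bg_vaq.copy()
        pval_col = bg_pval.copy()

        cs = CallSet(sample_id=config.sample_id, replicate_id=rep_id)

        # true variants: replicate-specific evidence and detection
        t_cov = coverage[true_pos - 1]
        t_vac = rng.binomial(t_cov, true_vaf)
        sf_p = stats.binom.sf(t_vac - 1, np.maximum(t_cov, 1), config.background_error)
        if config.dropout:
            detected = (t_vac >= config.detect_min_vac) & (sf_p < config.detect_pvalue)
        else:
            detected = np.ones(len(t_vac), dtype=bool)

        t_vaq = 35.0 * rng.beta(conc * q_true_prop, conc * (1 - q_true_prop))
        p_draw = rng.uniform(np.nextafter(0, 1), 1.0, size=len(t_vac))
        zero_mask = (t_vac >= config.pvalue_highvac_threshold) \
            & (rng.random(len(t_vac)) < config.pvalue_zero_mass)
        t_pval = np.where(zero_mask, 0.0, p_draw)

        for j in range(config.n_true_variants):
            pos = int(true_pos[j])
            cov_j = float(t_cov[j])
            vac_j = float(t_vac[j])
            vaf_j = vac_j / cov_j if cov_j > 0 else 0.0
            # consensus record reflects the raw evidence whether or not called
            idx = pos - 1
            vac_col[idx] = vac_j
            vaf_col[idx] = vaf_j
            vaq_col[idx] = t_vaq[j]
            pval_col[idx] = t_pval[j]
            if detected[j]:
                call[idx] = call_from_genotype(true_gt[j])
                cs.add(VariantCall(
                    chrom=chrom, pos=pos, ref=str(true_ref[j]),
                    genotype=true_gt[j], variant_allele=str(true_alt[j]),
                    coverage=cov_j, vac=vac_j, vaf=vaf_j,
                    vaq=float(t_vaq[j]), pvalue=float(t_pval[j]),
                    annotation=str(annotation[idx]),
                ))

        # independent false calls, low VAC/VAF, never shared by design
        n_false = rng.poisson(config.error_rate_per_replicate * n_bp)
        free = np.setdiff1d(np.arange(1, n_bp + 1), true_pos, assume_unique=False)
        f_pos = rng.choice(free, size=min(n_false, len(free)), replace=False)
        f_vac = rng.integers(1, 6, size=len(f_pos)).astype(float)
        f_vaq = 35.0 * rng.beta(2.5, 4.5, size=len(f_pos))
        f_pval = rng.uniform(np.nextafter(0, 1), 1.0, size=len(f_pos))
        f_alt_off = rng.integers(1, 4, size=len(f_pos))
        for j, pos in enumerate(f_pos):
            pos = int(pos)
            idx = pos - 1
            cov_j = float(max(coverage[idx], f_vac[j]))
            coverage[idx] = cov_j  # consensus row must satisfy vac <= coverage
            r_base = str(ref[idx])
            a_base = BASES[(base_idx[r_base] + int(f_alt_off[j])) % 4]
            gt = tuple(sorted((r_base, a_base)))
            vaf_j = f_vac[j] / cov_j
            call[idx] = call_from_genotype(gt)
            vac_col[idx] = f_vac[j]
            vaf_col[idx] = vaf_j
            vaq_col[idx] = f_vaq[j]
            pval_col[idx] = f_pval[j]
            cs.add(VariantCall(
                chrom=chrom, pos=pos, ref=r_base, genotype=gt,
                variant_allele=a_base, coverage=cov_j, vac=float(f_vac[j]),
                vaf=float(vaf_j), vaq=float(f_vaq[j]), pvalue=float(f_pval[j]),
                annotation=str(annotation[idx]),
            ))

        # consensus table: ambiguous where unsequenced or randomly failed
        ambiguous = (coverage == 0) | (rng.random(n_bp) < config.ambiguous_call_rate)
        call = np.where(ambiguous, "N", call)
        consensus = pd.DataFrame({
            "chrom": chrom, "pos": np.arange(1, n_bp + 1), "ref": ref,
            "call": call, "coverage": coverage.astype(float),
            "vac": vac_col, "vaf": np.round(vaf_col, 6),
            "vaq": np.round(vaq_col, 4), "pvalue": np.round(pval_col, 6),
        }).set_index(["chrom", "pos"]).sort_index()
        cs.consensus = consensus
        replicates.append(cs)

    reps = ReplicateSet(sample_id=config.sample_id, replicates=replicates,
                        batch_ids=[config.batch_id] * config.n_replicates)
    return reps, truth, GCTrack(gc_df)


def simulate_batches(configs: Sequence[SimulationConfig]
                     ) -> list[tuple[ReplicateSet, GroundTruth, GCTrack]]:
    """Simulate one replicate set per config; per-config ``batch_scale``
    models slide-to-slide variation in total reads (it multiplies every
    position's mean depth)."""
    if len(configs) < 2:
        raise ValueError("need at least 2 configs for a batch comparison")
    return [simulate_replicate_set(c) for c in configs]


def write_replicate_set(reps: ReplicateSet, truth: GroundTruth, gc: GCTrack,
                        outdir) -> list[Path]:
    """Write VCF + consensus TSV per replicate, the truth TSV and the GC
    track under ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for cs in reps.replicates:
        vcf = outdir / f"{reps.sample_id}_{cs.replicate_id}.vcf"
        write_vcf(cs, vcf)
        written.append(vcf)
        cons = outdir / f"{reps.sample_id}_{cs.replicate_id}_consensus.tsv"
        write_consensus_table(cs, cons)
        written.append(cons)
    truth_path = outdir / f"{reps.sample_id}_truth.tsv"
    truth.variants.to_csv(truth_path, sep="\t", index=False)
    written.append(truth_path)
    gc_path = outdir / f"{reps.sample_id}_gc.tsv"
    gc.windows.to_csv(gc_path, sep="\t", index=False)
    written.append(gc_path)
    return written
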