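# varconcord

Replicate concordance analysis of single-nucleotide-variant (SNV) calls.

When the same genomic DNA is sequenced twice — library preparation, target
capture and sequencing fully repeated — any disagreement between the two
call sets is technical noise. `varconcord` quantifies that noise for
targeted sequencing experiments and asks which properties of a call
predict whether it will reproduce. It is written for bioinformaticians
evaluating variant-calling pipelines and for anyone deciding how to filter
call sets when true variants are unknown.

## What it computes

**Concordance rate.** For a pair of replicate call sets with *N₁* and *N₂*
SNV calls, of which *N_c* are called in both with an identical genotype,

&nbsp;&nbsp;&nbsp;&nbsp;*R_c* = *N_c* / mean(*N₁*, *N₂*)

Triplicate samples are summarised by the unweighted mean of their three
pairwise rates. Whole-region concordance compares per-position consensus
genotypes, optionally excluding ambiguous (`N`) calls. Lin's concordance
correlation coefficient and Spearman's ρ cover agreement of per-sample
sequencing metrics, and Pearson's r the per-position coverage of a pair.

**Factor stratification.** Concordance is recomputed within categories of
coverage (fixed bins 1–4x, 5–19x, 20–79x, 80–199x, ≥200x), variant allele
count (VAC), variant allele frequency (VAF), variant allele quality (VAQ),
SNV-call p-value, GC content, substitution type and genome annotation.
Continuous factors are binned by Sturges' rule over the pooled SNV values
(log10 for VAC) with sparse tail bins merged inward; a position counts for
a factor only if it falls in the same bin in both replicates.

**Factor importance.** Each factor's association with the binary
concordance status is measured three ways: mutual information with the
binned factor, AIC of a univariate logistic regression, and the order in
which factors enter an L1-penalised logistic model as the penalty λ
decreases from λ_max (one-way ANOVA R² accompanies the stratified rates).

**Filter evaluation.** Threshold criteria (derived from the reproduced
group's means, or the preset coverage ≥ 20, VAC ≥ 20, VAF ≥ 0.3, VAQ ≥ 20)
are applied to both replicates and the before/after rates compared with a
paired t-test.

**Synthetic replicates.** A seeded generator produces replicate call sets
with ground truth: shared true variants (VAF mixture peaking near 1 with a
secondary peak near 0.5), negative-binomial coverage with a GC-content
penalty and batch scaling, detection dropout driven by sampled evidence,
and independent low-evidence false calls per replicate.

## Worked example

```python
from varconcord import SimulationConfig, simulate_replicate_set, snv_concordance

reps, truth, gc = simulate_replicate_set(SimulationConfig(seed=42))
r = snv_concordance(*reps.replicates)
print(f"Nc={r.n_concordant}, N1={r.n_total_1:.0f}, N2={r.n_total_2:.0f}, "
      f"Rc={100 * r.rate:.1f}%")
```

prints

```
Nc=838, N1=1185, N2=1206, Rc=70.1%
```

1000 true variants were planted and shared by both replicates, yet only
70.1% of calls reproduce: each replicate misses some true variants whose
sampled evidence falls below detection, and adds its own false calls.
Ranking the factors on the pooled calls of the same pair
(`examples/04_factor_importance.py`):

```
factor     MI (nats)      AIC
coverage     0.0109    2066.6
     vac     0.5570     403.9
     vaf     0.5262     596.2
     vaq     0.3401    1103.3
  pvalue     0.3682    1031.2
```

VAC has the largest mutual information and the smallest AIC — the variant
evidence itself, not raw depth, predicts whether a call reproduces.

The `examples/` directory holds one short script per capability
(reference-table rates, simulation, stratification, factor ranking,
filtering). A thin CLI wraps the pipeline:

```sh
varconcord all --config run.yaml --out results/ --seed 7
```

writes `concordance.tsv`, `stratified.tsv`, `association.json`,
`filtering.tsv` and `run.json` (version, seed, config hash).

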