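# Methods

## Concordance model

Two call sets from replicate sequencing of the same DNA are compared by
genotype at each position. A position contributes to the concordant count
*N_c* only when both replicates call an SNV there with an identical
unordered allele pair; a call present in one replicate only, or present in
both with different genotypes, is discordant. The rate is
*R_c* = *N_c* / mean(*N₁*, *N₂*), so a one-sided call inflates only its own
replicate's total. Triplicates are summarised by the unweighted mean of the
three pairwise rates. Empty pairs have no defined rate and raise an error
rather than returning 0 or NaN.

Whole-region concordance joins the two per-position consensus tables on
shared positions and compares call symbols (bases for homozygous calls,
IUPAC two-base codes for heterozygous, `N` for ambiguous). In the default
mode positions where either call is `N` are excluded. When ambiguous calls
are included, `N` vs a base counts as discordant and `N` vs `N` as
concordant; the study regime this mirrors reports including-ambiguous
rates of 97–99% with most discordance attributable to `N` calls, and the
`N`-vs-`N` convention is a documented choice, not something the reported
rates pin down.

Printed rates use half-up rounding at the reporting precision (1 decimal
for SNV rates, 4 for whole-region rates), computed in decimal arithmetic
so that exact halves round predictably.

Lin's concordance correlation coefficient is
2·cov(x,y) / (var x + var y + (x̄ − ȳ)²) with (n−1) variances; it is
attenuated relative to Pearson's r by location or scale shifts, which is
why it accompanies Spearman's ρ for per-sample metric agreement.

## Binning and stratification

Continuous factors are cut three ways:

* **coverage** — fixed empirical bins [1,5), [5,20), [20,80), [80,200),
  ≥200, matching the depth strata conventional in capture QC;
* **VAC, VAF, VAQ, p-value** — Sturges' rule, k = ⌈log₂ n + 1⌉ equal-width
  bins over the observed range of the pooled SNV values (VAC on the log10
  scale). The classical histogram implementation snaps edges to round
  numbers; edges here span [min, max] exactly, so bin counts can differ by
  ±1–2 from a snapped histogram of the same data;
* **GC content** — two classes split at 50%, assigned from the windowed
  track containing the position; **substitution type** (12 ordered ref>alt
  categories; transitions are A>G, G>A, C>T, T>C) and **annotation** (10
  classes) are natural categories.

Tail bins holding fewer than max(30, 0.1% of positions) values are folded
into their inward neighbour, repeatedly, until the outermost bin meets the
threshold; interior bins are never merged, and the result is a coarsening
(no value changes relative order).

Stratified concordance applies the same-bin pairing rule: a position
enters a factor's analysis only when its value lies in the same bin in
both replicates, and is otherwise disregarded for that factor. Per
replicate, the value comes from the replicate's own variant record, or
from its consensus record when the position was not called there. For
categorical factors only calling replicates carry a value; the calling
replicate's category is used for both sides, and a pair calling two
different categories is disregarded.

## Association measures

Calls from all pairs are pooled with status 1 (reproduced) / 0 (not
reproduced). The factor value of a pooled row is the mean of the two
replicates' values — the source regime does not state how a single value
per position was chosen; the mean is symmetric and uses the consensus
value when one replicate lacks a call.

* **Group comparison** — mean ± sd per status group, Welch two-sided
  t-test.
* **R²** — one-way ANOVA SS_between/SS_total over per-pair per-bin rates;
  the p-value comes from the standard F test on bins with ≥2 rates.
* **Mutual information** — plug-in estimate over the joint counts of
  status × bin, in nats (0·ln 0 := 0); bits are a secondary column. The
  plug-in estimator is biased upward at small counts, which is acceptable
  here because only the ranking across factors is interpreted.
* **AIC** — univariate logistic regression by maximum likelihood;
  AIC = 2k − 2 ln L̂ with k = 2 by model definition, including for a
  degenerate (constant) factor where the fit is rank-deficient. Perfect
  separation falls back to a lightly ridge-penalised refit and is flagged.
* **Lasso entry order** — predictors standardised to unit variance;
  λ grid of 100 log-spaced points from λ_max = maxⱼ |xⱼᵀ(y − ȳ)|/n down to
  10⁻³ λ_max. A factor's entry λ is bracketed on the grid and refined by
  bisection (20 geometric halvings), so ties survive only when genuinely
  identical. Exactly duplicated predictors (|correlation| = 1 after
  standardisation) enter at the same λ by symmetry but are assigned
  arbitrarily by the solver, so they are detected beforehand, fitted
  through one representative and reported as an explicit tie. Classes are
  left unweighted.

## Filtering

`apply_filter` keeps calls meeting every lower-bound threshold (and an
optional p-value upper bound); it is idempotent, monotone in the criteria,
and logs per-rule removal counts. Calls missing a thresholded field are
dropped and logged by default (configurable). The pooled-criteria deriver
uses the reproduced group's mean per factor (counts rounded to integers,
VAF to one decimal); the shipped presets are {78, 45, 0.6, 22} for the
pooled family and {20, 20, 0.3, 20} for the categorized family, the latter
strictly weaker field-wise. `filter_effect` reports per-pair before/after
rates and a two-sided paired t-test, with a NaN p-value flagged when the
filter changes nothing. Read-level duplicate removal is upstream; pre- and
post-dedup call sets are simply two inputs.

## Synthetic replicate generator

The generator's defaults describe a 50 kb slice of an exon-capture target
at mean depth 80x with 1000 true variants and per-replicate false calls at
0.006/bp (~30% of the true count) — a deliberately dense, scaled-down
version of a ~3.2 Mb kinome screen, chosen so that association and
filtering statistics are estimable from a single simulated pair.

* **True VAF mixture** — 0.60 homozygous-like Beta(40,2) (peak near 1),
  0.25 heterozygous Beta(60,60) (peak at 0.5), 0.15 low-frequency tail
  Beta(2,8). The emulated study describes the peaks only qualitatively;
  the weights are configuration, not calibrated values.
* **Coverage** — per-position mean = 80 × GC penalty (×0.34 in windows
  with GC > 50%) × exon boost (×1.5) × batch scale × a shared
  capture-efficiency Gamma(3, 1/3) propensity; each replicate then draws
  negative-binomial (size 5) counts around that mean. The shared
  propensity is what makes replicate coverage correlate (~0.66, inside the
  0.29–0.77 range observed in practice) and keeps coverage thresholds from
  splitting true calls across replicates.
* **Detection dropout** — a true variant is emitted in a replicate only if
  its sampled VAC (Binomial(coverage, VAF)) is ≥2 **and** a binomial test
  against a 5% background mismatch rate gives p < 10⁻⁴. Dropout — hence
  discordance — is therefore causally driven by coverage and VAC, and
  stratified concordance rises with depth until dropout vanishes, then
  plateaus.
* **False calls** — Poisson(0.006 × target) per replicate at non-variant
  positions, VAC uniform on 1–5, never shared between replicates.
* **VAQ** — 0–35 scale; each replicate draws Beta-distributed values
  (concentration 60) around a shared per-position propensity, Beta(6,2.5)
  for true variants (mean ≈ 25) and Beta(2,5) background; false calls draw
  independently from Beta(2.5,4.5) (mean ≈ 12.5).
* **p-values** — calls with VAC ≥ 10 receive an exact 0 with probability
  0.91, all others Uniform(0,1].
* **Consensus tables** — every target position, with the raw sampled
  evidence recorded whether or not the variant was called, ambiguous `N`
  at 2% of positions or where coverage is 0.

All draws come from a single `numpy` generator seeded by the config, so
identical configurations are byte-identical.

**What the generator does not emulate:** read-level artifacts (mapping
bias, strand bias, PCR duplicates), indels, genotype miscalls between
co-detected replicates, and the real study's variant density (1000/50 kb
vs ~1000/3.2 Mb). Whole-region concordance on synthetic data is therefore
~98.5–99%, not >99.99%: discordant variant positions are ~60× denser than
in a real screen. Tests passing on synthetic data show the statistics and
their causal wiring are computed correctly, not that any particular
platform reaches a given concordance.

## Numerical and design choices

* Coordinates are 1-based fully closed; BED converts on read. Genotypes
  are unordered pairs; IUPAC codes decode to heterozygous pairs; `N` is
  never a variant.
* The consensus TSV dialect (`#chrom pos ref call coverage vac vaf vaq
  pvalue`, `.` for missing) is this package's own documented stand-in for
  proprietary consensus formats; the `ref` column is required so that
  "non-reference" is decidable row-locally.
* Numeric bins are left-closed right-open with the final bin closed above;
  values outside a scheme map to no bin and are dropped from that factor's
  analysis.
* Degenerate inputs fail loudly: empty pairs, single replicates, single
  bins, single-class status tables and sub-minimal vectors all raise.
* Sub-sampled problem sizes throughout the test-suite (10–50 kb targets,
  20 seeded runs) are the package's chosen desk-scale study conditions.

## Known limitations

* Sturges bin edges are not identical to snapped-histogram edges, so bin
  counts on real data may differ slightly from analyses done with
  plotting-library defaults.
* The plug-in MI and the unpenalised logistic AIC are both sample-size
  dependent; comparisons are meaningful within one pooled table, not
  across tables of different sizes.
* Lasso entry order can be unstable between strongly (but not perfectly)
  correlated factors; the refined entry λ values should be read alongside
  the MI and AIC columns, as the three methods' agreement is the robust
  signal.
* `filter_effect` excludes pairs emptied by a filter, which biases the
  after-mean upward if many pairs vanish; the count of excluded pairs is
  reported for exactly that reason.
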