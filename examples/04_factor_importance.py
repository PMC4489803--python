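"""Rank the call-evidence factors by association with concordance status.

Every SNV position of a replicate pair is labelled concordant (1) or
discordant (0); three methods then rank the factors: mutual information
with the binned factor (larger = stronger), AIC of a univariate logistic
model (smaller = stronger), and the order in which factors enter an
L1-penalised logistic model as the penalty relaxes (earlier = stronger).
"""

from varconcord.association import (
    lasso_entry_order,
    mutual_information,
    pool_status,
    univariate_aic,
)
from varconcord.pipeline import build_schemes
from varconcord.simulate import SimulationConfig, simulate_replicate_set

FACTORS = ["coverage", "vac", "vaf", "vaq", "pvalue"]

reps, _, _ = simulate_replicate_set(SimulationConfig(seed=1))
tab = pool_status(reps.pairs())
schemes = build_schemes(tab)

print(f"pooled SNV positions: {len(tab)} "
      f"({int(tab.status.sum())} concordant, {int((1 - tab.status).sum())} discordant)\n")
print("factor     MI (nats)      AIC")
for f in FACTORS:
    mi = mutual_information(tab, f, schemes[f])
    aic = univariate_aic(tab, f).aic
    print(f"{f:>8}   {mi:8.4f}  {aic:8.1f}")

entries = lasso_entry_order(tab, FACTORS)
print("\nlasso entry order (first = most associated):")
for e in entries:
    lam = "never" if e.entry_lambda is None else f"lambda={e.entry_lambda:.4g}"
    tie = f"  (tied with {', '.join(e.tied_with)})" if e.tied_with else ""
    print(f"  {e.rank}. {e.factor_name} ({lam}){tie}")

print("\nVariant allele count and frequency carry the most information about")
print("whether a call reproduces - they are the evidence the caller acts on.")
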