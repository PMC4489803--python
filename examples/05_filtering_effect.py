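"""Effect of evidence-threshold filtering on replicate concordance.

The categorized preset (coverage>=20, VAC>=20, VAF>=0.3, VAQ>=20) comes
from reading stratified concordance curves; applying it to both
replicates of each pair and recomputing Rc shows how much discordance
lives in low-evidence calls.
"""

from varconcord.filtering import categorized_criteria, filter_effect
from varconcord.simulate import SimulationConfig, simulate_replicate_set

pairs = []
for seed in range(8):
    reps, _, _ = simulate_replicate_set(
        SimulationConfig(seed=seed, sample_id=f"S{seed}"))
    pairs.append(reps.pairs()[0])

criteria = categorized_criteria()
eff = filter_effect(pairs, criteria)

print(f"criteria: coverage>={criteria.min_coverage:.0f}, VAC>={criteria.min_vac:.0f}, "
      f"VAF>={criteria.min_vaf}, VAQ>={criteria.min_vaq:.0f}")
print(f"pairs: {len(eff.rates_before)}")
print(f"mean Rc before filtering: {100 * eff.mean_before:.1f}% (sd {100 * eff.sd_before:.1f})")
print(f"mean Rc after  filtering: {100 * eff.mean_after:.1f}% (sd {100 * eff.sd_after:.1f})")
print(f"paired t-test (two-sided): p = {eff.paired_t_pvalue:.2g}")
print()
print("False calls carry low VAC/VAF by nature, so thresholding the call")
print("evidence removes mostly discordant calls and raises concordance.")
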