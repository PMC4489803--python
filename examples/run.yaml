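# Pipeline configuration for `varconcord all --config examples/run.yaml`.
# Exactly one of `simulate:` / `samples:` supplies the input; `samples:`
# maps sample ids to 2-3 consensus-table paths (one per replicate).
out_dir: results/run
seed: 7
simulate:
  n_samples: 4
  n_target_bp: 20000
  n_true_variants: 400
filter_preset: categorized   # categorized | pooled | pooled_preset
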