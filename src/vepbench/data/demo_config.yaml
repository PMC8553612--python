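# Demo run: five synthetic gene strata at the published sizes and
# deleterious fractions, three synthetic tools, default threshold specs.
seed: 17
simulate:
  gene_profiles: default
  tool_profiles: default
  clinvar_plp_rate: 0.15
  clinvar_blb_rate: 0.02
specs_file: default
bands:
  tools: [metaA]
  threshold: 0.7
options:
  auc_mode: raw
  lr_pooling: arithmetic
  dropout_denominator: definite
  min_coverage: 0.25
  step_fraction: 0.02
  top_k: 12
  threeway:
    - [metaA_b, lowB_a, catC_a]
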