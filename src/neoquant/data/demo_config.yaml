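# Demo pipeline configuration: a deliberately small synthetic cohort so the
# full simulate -> report run finishes quickly on one CPU.  The simulator's
# library defaults describe the full published-cohort scale; the demo scales
# the burden and proteome down while keeping every stage exercised.
simulate:
  n_patients: 30
  seed: 7
  burden_median: 25
  burden_sigma: 0.7
  n_genes: 30
  gene_length_range: [100, 200]
  oncogene_frac: 0.1
  tcr_n_clones: 300
  tcr_total_templates: 3000
predict:
  predictor: mock
features:
  frequency_denominator: hvsnv
  exome_mb: 34.0
  score_quality: true
survival: {}
riskmodel:
  horizon_months: 36
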