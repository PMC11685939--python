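{
  "cohort": {
    "n_aml": 40,
    "n_hd": 12,
    "events_per_sample": 2000,
    "noise_cv": 0.2,
    "seed": 1
  },
  "stages": ["simulate", "redox", "scenith", "ev", "lipids", "correlate"],
  "reference_population": "CD3",
  "threshold_quantile": 0.5,
  "target_population": "CD34",
  "roc_marker": "CD44",
  "outdir": "results/pipeline"
}
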