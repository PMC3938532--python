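# Run configuration for the numbered analysis scripts.
# Merged over the package defaults (channelfauna.pipeline.DEFAULT_CONFIG).
seed: 1
output_dir: results/analysis

# 2,500 background points over 5 contour strata and 5-fold cross-validation
# keep a laptop run of the whole analysis to a few minutes while preserving
# every mechanism; the library defaults (10,000 points, 25 folds) match the
# full-scale protocol.
background:
  n: 2500
maxent:
  k_folds: 5
  n_knots: 5
  max_sweeps: 500
  jackknife: true
  jackknife_k: 0
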