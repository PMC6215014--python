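# Demo pipeline configuration: a small synthetic world, the full
# DHI -> clustering -> evaluation chain, and reduced resampling so the
# run finishes in under a minute.
seed: 11
world:
  grid_rows: 64
  grid_cols: 128
  n_archetypes: 6
cluster:
  n_clusters: 6
  k_pre: 150
  cut: dynamic
  sieve_min_pixels: 20
evaluate:
  n_per_region: 100
  reps: 50
  alpha: 0.05
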