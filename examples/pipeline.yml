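# Full pipeline: simulate a two-timepoint cohort with a planted 3 -> 5
# cluster transition, cluster both timepoints, soft-stratify, estimate the
# transition model. Run with:
#   sigstrat run --config examples/pipeline.yml --out-dir scratch/run
seed: 42
simulate:
  t1_mixture:
    n_points: 750
    n_dims: 5
    n_clusters: 3
    separation: 8.0
  transition:
    - [0.70, 0.20, 0.10, 0.00, 0.00]
    - [0.10, 0.20, 0.40, 0.20, 0.10]
    - [0.00, 0.05, 0.10, 0.25, 0.60]
  t2_centroids:
    - [ 8.0,  0.0,  0.0,  0.0,  0.0]
    - [ 0.0,  8.0,  0.0,  0.0,  0.0]
    - [ 0.0,  0.0,  8.0,  0.0,  0.0]
    - [ 0.0,  0.0,  0.0,  8.0,  0.0]
    - [ 0.0,  0.0,  0.0,  0.0,  8.0]
  t2_within_sd: 1.0
cluster:
  timepoints: [t1, t2]
stratify:
  temperature: 1.0
trajectory:
  t1: t1
  t2: t2
  mode: hard
  alpha: 0.5
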