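# sigstrat

Stratified-psychiatry analysis toolkit: patients are represented as points in
multidimensional **signature spaces** (one axis per clinical item or marker),
treatment-relevant subgroups are discovered as density-peak **prototypes**,
patients are stratified by hard or soft distance-based membership, treatment
response is modelled as probabilistic **trajectories** between clusters at two
timepoints, and outcomes are defined as **regions** of signature space instead
of thresholds on collapsed univariate scores.

## What's in the box

| module | purpose |
| --- | --- |
| `sigstrat.scales` | scale definitions, cohort I/O (wide/long CSV), Euclidean distances, summed per-domain scores, z-scoring |
| `sigstrat.density_peaks` | density-peak clustering: local density `rho`, separation `delta`, prototype selection (`gamma_gap` / `threshold` / `fixed_k`), nearest-prototype or chain assignment |
| `sigstrat.stratify` | hard/soft assignment to prototypes, Bayes priors, closed-form Fisher linear discriminants |
| `sigstrat.trajectories` | cluster-transition CPT estimation (hard or soft counts, Dirichlet smoothing) and soft-evidence queries |
| `sigstrat.regions` | outcome regions: closed balls, discriminant half-spaces, unions; cohort response rates |
| `sigstrat.simulate` | seeded generators: bimodal treatment response, planted Gaussian mixtures, two-timepoint cohorts with a planted transition matrix |
| `sigstrat.rubric` | 0–5 trial-readiness scoring rubric plus an encoded reviewed-trials fixture |
| `sigstrat.cli` | `sigstrat` command with `simulate`, `cluster`, `stratify`, `trajectory`, `predict`, `evaluate`, `score-trials`, `run` |

## CLI walkthrough

```sh
# 1. simulate a bimodal-response cohort (100 patients, 2 axes, 2 timepoints)
sigstrat simulate bimodal --seed 42 --out scratch/demo

# 2. cluster the follow-up signatures into two groups
sigstrat cluster --input scratch/demo_cohort.csv --scale examples/totals.yml \
    --timepoint t2 --selection fixed_k --k 2 --out scratch/clusters.csv

# 3. soft-stratify against the discovered prototypes
sigstrat stratify --input scratch/demo_cohort.csv --scale examples/totals.yml \
    --timepoint t2 --prototypes scratch/clusters_prototypes.csv \
    --mode soft --temperature 1.0 --out scratch/memberships.csv

# 4. estimate a transition model from membership tables at both timepoints
sigstrat trajectory --t1 scratch/m1.csv --t2 scratch/m2.csv \
    --mode hard --alpha 0.5 --out scratch/model.json

# 5. soft-evidence query: where does a new patient end up?
sigstrat predict --model scratch/model.json --membership scratch/m1.csv \
    --out scratch/predicted.csv

# 6. evaluate follow-up signatures against an outcome region
sigstrat evaluate --input scratch/demo_cohort.csv --scale examples/totals.yml \
    --timepoint t2 --region examples/region.yml --out scratch/response.csv

# 7. score registered trials on the 0-5 stratification-readiness rubric
sigstrat score-trials --out scratch/scores.csv
```

A whole pipeline (simulate → cluster → stratify → trajectory → evaluate) can
be declared in one YAML file and run with `sigstrat run --config pipeline.yml
--out-dir scratch/run`; every run writes a `manifest.json` recording inputs,
outputs, settings, seed and output checksums, and a rerun with the same
config is bit-identical.

A scale definition file looks like:

```yaml
name: panss
items: [p1, p2, ..., g16]
domains:
  positive: [p1, ..., p7]
  negative: [n1, ..., n7]
  general:  [g1, ..., g16]
item_range: [1, 7]
```

and a region file like:

```yaml
kind: ball          # or halfspace / union
center: [5.0, 20.0]
radius: 8.0
```

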