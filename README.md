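# partclus

Design effects, sample-size planning and simulation-based validation for
**two-arm parallel partially clustered trials** — trials that mix
independent observations (clusters of size 1) with pre-existing clusters
of varying sizes (twins and triplets, paired organs, repeated
enrolments in re-randomisation designs) — analysed by GEE with an
independence or exchangeable working correlation and the robust sandwich
variance.

## What it does

- **`partclus.distributions`** — cluster-size mixes: convert between
  unit-level proportions `gamma` and cluster-level proportions `delta`,
  and turn observation targets into cluster (recruitment) targets.
- **`partclus.design_effects`** — design effects (DEFFs) three ways:
  randomisation-specific closed forms (continuous and binary outcomes,
  logit and log links), allocation-level formulas taking per-cluster
  treated/control splits, and a direct matrix evaluation of the sandwich
  covariance at the true parameters that serves as the normative oracle.
- **`partclus.sample_size`** — independent-data sample sizes (two-sample
  t; chi-square with/without continuity correction), DEFF inflation,
  recruitment conversion and expected power via the effective sample
  size (noncentral-t for continuous outcomes, Wald log-OR/log-RR for
  binary).
- **`partclus.gee_engine`** — fast GEE fits of the unadjusted marginal
  model with sandwich and model-based covariances, moment-estimated
  exchangeable correlation, non-convergence/non-positive-definite
  flagging, and observed DEFFs.
- **`partclus.synthetic_data`** — design realisation (fixed or
  multinomial cluster counts), cluster- or individual-level
  randomisation under strict or relaxed balance, random-intercept
  normal outcomes, and exchangeable correlated Bernoulli outcomes with
  arm-specific prevalences (conditional-linear-family construction with
  feasibility checking).
- **`partclus.sim_study`** — scenario grids comparing observed
  (simulated) DEFFs and power against the closed-form expectations.

## Library quick start

```python
import partclus as pc

dist = pc.ClusterSizeDistribution.from_gamma([0.70, 0.25, 0.05])
spec = pc.DesignSpec("cluster", "exchangeable", "binary", rho=0.5,
                     pi_i=0.14, pi_c=0.20)
effect = pc.EffectSpec("binary", pi_i=0.14, pi_c=0.20, alpha=0.05, power=0.80)

result = pc.plan(spec, dist, effect)
result.n_independent_per_group   # 647
result.n_observations_per_group  # 725  (DEFF 1.12)
result.n_clusters_per_group      # 611 clusters to recruit per group
```

## Command line

```bash
# closed-form design effect
partclus deff --outcome continuous --randomization cluster \
    --working independence --gamma 0.70,0.25,0.05 --rho 0.5

# full sample-size plan (flags or --config plan.yaml; flags win)
partclus samplesize --outcome binary --randomization cluster \
    --working exchangeable --gamma 0.70,0.25,0.05 --rho 0.5 \
    --pi-c 0.2 --pi-i 0.14 --power 0.8

# one synthetic trial dataset as CSV
partclus generate --counts 280,60,40,20 --randomization cluster \
    --outcome continuous --rho 0.2 --seed 1 --out trial.csv

# scenario grid (YAML with a `scenarios:` list), one summary row per
# scenario x working correlation
partclus simulate --config grid.yaml --reps 2000 --seed 1 --out results.csv
```

Vectors passed on the command line are comma-separated and must be
declared as `--gamma` (unit-level) or `--delta` (cluster-level) — never
inferred. All commands emit JSON/CSV; validation errors exit with
status 2.

## Notes

- Closed forms assume 0 ≤ ρ < 1 (exchangeable) as in the source
  derivations; the matrix oracle accepts any ρ > −1/(K−1).
- Exchangeable GEE fits whose estimated correlation falls outside
  [−1, 1] are flagged `non_positive_definite` but retained, matching the
  validation protocol the package replicates.
- Simulated datasets are long-format CSV (`cluster_id`, `member_id`,
  `arm`, `y`); identical seed + configuration gives byte-identical data.
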