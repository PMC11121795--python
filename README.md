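# exogem

Construct patient-specific genome-scale metabolic models (GEMs) from
*relative* plasma-metabolome data, and analyze them end to end:

1. **Baseline characterization** — sample the feasible flux space of a
   curated GEM (artificially-centered hit-and-run behind a pluggable
   sampler contract) and locate the densest region of the sampled
   solutions via pairwise-distance density scoring with a dynamic,
   non-arbitrary percentile threshold (continuous and discrete methods).
   The chosen threshold, the retained-solution count and the
   central-furthest span are saved and reused by later stages.
2. **Exometabolome integration** — rescale the baseline exchange-reaction
   envelope by patient/control concentration ratios (min / mean / max
   control statistics give three models per patient), sample each model,
   fuse the clouds, and build a consensus patient-specific GEM.
3. **Characterization** — metabolic-task analysis by FBA, leave-one-
   metabolite-out cross-validation (Welch t-test + Benjamini-Hochberg),
   essentiality / synthetic-lethality scans (FBA, ROOM-style and
   density-based flux predictors), perturbation-sweep sensitivity cubes,
   PLS-DA, and hierarchical patient stratification.

A hand-authored 22-reaction toy network plus a synthetic-cohort
simulator (`exogem.synthetic`) make every stage testable offline.

## Library quick start

```python
from exogem.model import load_model, set_biomass_floor
from exogem.sampling import sample_fluxes
from exogem.resos import run_resos
from exogem.integrate import baseline_profile
from exogem.synthetic import make_toy_model

model = set_biomass_floor(make_toy_model(), 0.5)
samples = sample_fluxes(model, 5000, seed=1)
scores, result = run_resos(samples, method="continuous")
profile = baseline_profile(model, samples, result)   # retained flux envelope
print(result.percentile, result.params.retained_count, result.params.span)
```

`exogem.pipeline.run_cohort_pipeline` runs baseline → patient trios →
consensus → tasks → clustering on an in-memory model + cohort.

## Command line

```bash
exogem synth --out-dir demo --seed 1          # toy model, tasks, cohort TSVs
exogem sample demo/toy_model.json --n-points 2000 --seed 1 --out demo/s.tsv
exogem resos demo/s.tsv --out demo/resos.json
exogem baseline demo/toy_model.json --out demo/profile.json
exogem tasks demo/toy_model.json --tasks demo/toy_tasks.json --out demo/t.tsv
exogem knockout demo/toy_model.json --out demo/scan.tsv
exogem run --config config.yaml --out-dir results/run1   # full pipeline
```

A pipeline config looks like:

```yaml
seed: 1
model: toy                 # or a path to SBML / COBRA JSON
cohort:
  synth:
    n_groups: 4
    patients_per_group: 6
    n_controls: 15
    n_metabolites: 8
    metabolite_names: [met_a, met_o, met_n, met_r, met_p, met_q, met_s, met_de]
    control_log_sd: 0.05
    effects:
      D: {metabolites: [met_a, met_o], fold_change: 3.0}
tasks: toy                 # or a path to a task JSON/TSV
sampling: {n_baseline: 2000, n_patient: 600, thinning: 5}
biomass_floor: 0.5
```

Every run writes a `manifest.json` (config/model digests, seed, outputs);
identical config + seed reproduce byte-identical TSV outputs.

## Layout

| module | role |
|---|---|
| `exogem.model` | GEM representation, SBML/JSON I/O, FBA/FVA, deletions |
| `exogem.sampling` | warmup, hit-and-run sampling, adaptive stopping on saved parameters |
| `exogem.resos` | density scoring, central/furthest solutions, dynamic percentile, filtering |
| `exogem.integrate` | control ratios, boundary rescaling, patient trios, consensus models |
| `exogem.tasks` | task definitions/evaluation, rank-change task selection |
| `exogem.knockout` | pruning, essentiality, synthetic lethality, ROOM, GPR mapping |
| `exogem.validation` | leave-one-out cross-validation, BH-FDR |
| `exogem.sensitivity` | perturbation sweeps, slope cubes, PLS-DA, PCA checks |
| `exogem.stratify` | complete-linkage clustering, row standardization, group contributions |
| `exogem.synthetic` | toy GEM fixture, synthetic cohorts with planted effects |
| `exogem.pipeline` / `exogem.cli` | orchestration, manifests, subcommands |
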