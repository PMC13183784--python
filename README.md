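# harvestlab

Individual-based simulation and estimation toolkit for size-dependent
harvest experiments on iteroparous fish populations.

The package couples a weekly-resolution individual-based simulator of
size-structured populations under three harvest regimes — *positive*
(remove a proportion P of fish above a length threshold), *negative*
(remove P of fish at-or-below it) and *random* (remove P/2 irrespective of
size) — with the estimators needed to analyse such experiments:

- **`harvestlab.ibm`** — the simulator: growth, maturation, reproduction,
  natural mortality, size-selective harvest, phenotypic censuses and
  marked-cohort tracking.
- **`harvestlab.maturation`** — logistic maturity ogives (L50/L25/L75),
  becoming-mature schedules (Lp50), odds-ratio contrasts between groups.
- **`harvestlab.growth`** — biphasic growth model (juvenile vs adult phase
  discounted by reproductive investment): forward map, nonlinear
  least-squares fitting of (c, r), and the log-log weight–length allometry.
- **`harvestlab.demography`** — directly observed mortality, mark-recapture
  total natural mortality from cohort decay
  (`N_{t+1} = exp(-mu dt) * P_hs * N_t`), life-table generation time, and
  elasticity of traits to biomass change.
- **`harvestlab.rates`** — phenotypic rates of change in haldanes with
  bootstrap confidence intervals.
- **`harvestlab.pipeline`** / **`harvestlab.cli`** — multi-phase,
  multi-regime experiment orchestration and per-regime report tables.

## CLI

```sh
# simulate the default five-phase experiment (3 regimes x 3 replicates)
harvestlab simulate --out out/sim --seed 1 --replicates 3

# run every estimator on the stored tables and write report CSVs
harvestlab estimate --data out/sim --out out/report --seed 1

# print the report
harvestlab report --data out/report

# or everything at once
harvestlab all --out out --seed 1
```

A YAML config can override the simulation parameters and the phase plan:

```yaml
sim:
  harvest_proportion: 0.4
  natural_mortality_week: 0.025
plan:
  replicates: 3
  phases:
    - {label: baseline, duration_weeks: 30, cycle_weeks: 6, harvest: false}
    - {label: harvest1, duration_weeks: 167, cycle_weeks: 6, harvest: true, mark_cohorts: true}
```

Outputs are tidy CSV tables (`census.csv`, `deaths.csv`, `harvests.csv`,
`cohorts.csv`, `abundance.csv`, `births.csv`) plus a plain-text run
manifest; identical seeds give byte-identical files.

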