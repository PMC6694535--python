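# cvdsim

Age-structured system-dynamics simulation of population-level cardiovascular
disease (CVD) outcomes under risk-factor management policies.

The model couples three compartmental risk-factor sub-models — a two-stage
disease structure for diabetes and hypertension (healthy → pre-stage →
disease, with managed/unmanaged splits) and a three-state smoking model
(never / current / former) — to an eight-risk-group CVD event engine.
Each risk group (every combination of diabetes, hypertension, smoking)
carries a logistic annual event probability in age and sex, adjusted for the
fraction of each constituent risk factor under management. Annual CVD
events, event deaths, the post-CVD survivor stock and age-adjusted incidence
are projected from 2010 to 2040 under a base case and four policy scenarios
(raised diabetes-management uptake, raised hypertension-management uptake,
raised smoking cessation, and all three combined), with ±50% Monte-Carlo
sensitivity on the incidence/initiation rates.

## Layout

| module | role |
|---|---|
| `cvdsim.demography` | cohort grids, births/deaths/migration/aging bookkeeping |
| `cvdsim.risk_factors` | two-stage disease and smoking stock-flow sub-models |
| `cvdsim.cvd_engine` | risk-group partition, event probabilities, treatment adjustment, post-CVD stock |
| `cvdsim.calibration` | risk-group intercept calibration, transition-rate fitting |
| `cvdsim.simulate` | composed annual simulation loop |
| `cvdsim.experiments` | scenario specs, scenario comparison, Monte-Carlo sensitivity |
| `cvdsim.synthetic_data` | synthetic demography/targets with known ground truth |
| `cvdsim.cli_io` | validated config (packaged defaults), CSV/JSON/report output, CLI |

## Command line

```bash
cvdsim synth --out synthetic --scale 0.01      # write fixture input files
cvdsim simulate --scenario base --out results/base.csv
cvdsim calibrate --out results/calibration.json
cvdsim scenarios --out results/scenarios.md    # all five scenarios + table
cvdsim sensitivity --runs 500 --seed 1 --out results/sensitivity.json
cvdsim report --results results/base.csv --out results/report.md
```

## Notable conventions

- All rates are annual fractions applied by explicit Euler steps (dt = 1
  year by default); a config switch reinterprets them as hazards.
- Two treatment-adjustment conventions are implemented: the default
  multiplies the treated fraction's event probability by the relative risk
  RR; `modes.eq10_literal: true` multiplies by (1 − RR) instead. The
  synthetic fixture uses the literal convention, which is the one consistent
  with the published scenario ordering.
- Risk-group shares are built from marginal prevalences assuming
  independence by default (`modes.partition_mode: even_split` gives an
  IPF-reconciled even-split allocation instead).
- The packaged default parameter table lives at
  `src/cvdsim/data/default_params.yaml`; every key is bounds-checked and
  unknown keys are rejected.
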