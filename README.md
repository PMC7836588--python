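# arfcea

Probabilistic decision-analytic cost-utility model comparing **prehospital
CPAP** with **standard oxygen therapy** for acute respiratory failure (ARF),
with probabilistic sensitivity analysis (PSA), cost-effectiveness
acceptability curves (CEAC) and value-of-information analysis
(EVPI / two-level Monte Carlo EVPPI).

The model is a two-strategy decision tree. The standard-care arm carries
baseline 30-day death and intubation risks; the CPAP arm obtains its risks
by applying log odds ratios to the baseline odds
(`expit(logit(p0) + logOR)`). Every patient incurs the hospitalisation
cost, intubation adds critical-care cost, and survivors accrue annual care
costs and QALYs over an already-discounted life expectancy. All ten model
parameters are uncertain (beta / gamma / normal / empirical-sample
distributions) and are propagated by Monte Carlo.

Two built-in scenarios:

- `acute` — effectiveness from the pilot randomised trial
  (log-OR Normal(0.145, 0.521) for mortality, Normal(0.591, 1.403) for
  intubation);
- `nma` — effectiveness from an updated network meta-analysis, emulated as
  normal pseudo-posterior samples on the log-odds scale with means
  `ln 0.5` / `ln 0.4` and sds derived from the published 95% credible
  intervals.

## CLI

```bash
# PSA bundle: psa.csv, ce_plane.csv, ceac.csv, incremental.csv, summary.csv
arfcea run-psa --scenario acute --n-iterations 100000 --seed 1 --out out/base

# Value of information: voi.csv (EVPI + per-parameter EVPPI)
arfcea run-voi --scenario nma --lambda 20000 --n-outer 1000 --n-inner 1000 \
    --seed 1 --out out/voi --undiscounted-population

# Emit a built-in scenario as an editable YAML config
arfcea dump-config --scenario acute > my_scenario.yaml
arfcea run-psa --scenario config:my_scenario.yaml --n-iterations 10000 \
    --seed 1 --out out/custom
```

Every run writes a `manifest.json` (scenario, seed, iteration counts,
thresholds, population assumptions) from which the run can be reproduced
byte-for-byte.

## Python API

```python
import arfcea as a

params = a.builtin_acute_parameters()
psa = a.run_psa(params, n_iterations=100_000, seed=1)
summary = a.summarize(psa)
icer = a.incremental_icer(summary.mean_cost, summary.mean_qaly)
curve = a.ceac(psa, a.default_lambda_grid())
evpi = a.evpi_per_person(psa, lam=20_000)
evppi = a.evppi_2level(params, ["logor_death"], lam=20_000,
                       n_outer=1000, n_inner=1000, seed=1)
```

The `synthetic_data` module (`simulate_trial`, `distributions_from_trial`,
`recovery_experiment`) generates two-arm binomial trial outcomes with the
assumed data-generating structure and rebuilds the beta baselines and
Woolf log-OR normals from the counts, supporting end-to-end tests with no
external data.

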