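# piedpiper

State-space detection of social ("pied-piper") effects of pulsed hatchery
releases on the daily downstream migration of wild salmon smolts.

## The problem

Hatcheries release tens of thousands of juvenile salmon into rivers over a
few days. Trap operators have long suspected that these pulses socially
stimulate wild smolts to migrate with them. Testing that against daily trap
counts is delicate: wild and hatchery fish share environmental cues (flow,
temperature, time of season) that can make both move on the same days, the
counts are autocorrelated and noisy, and traps are often pulled exactly when
the hatchery pulse arrives.

This package implements the full analysis chain for that question, for
anyone working with smolt-trap count data: covariate engineering from raw
trap and gauge tables, a multivariate autoregressive state-space (MARSS)
model fitted by Kalman maximum likelihood, AICc model selection with
Akaike-weight variable importance, and sensitivity analyses for the
unmarked-hatchery-fish confound. Because real trap datasets are typically
not public, it ships a synthetic-data generator with known ground truth that
reproduces the statistical structure of such data, so the whole chain is
exercisable and verifiable end to end.

## The model

For each chain (one year × day/night period), with `y_t` the standardized
log catch-per-unit-effort of wild smolts and `c_t` the standardized
covariates,

    y_t = x_t + v_t,              v_t ~ N(0, r)      (observation)
    x_t = x_{t-1} + B c_t + w_t,  w_t ~ N(0, q)      (process)

Chains are independent with diagonal Q and R; environmental coefficients in
`B` are shared across all chains, the social (hatchery-difference)
coefficient optionally splits day/night, and q is shared or per-period. The
social covariate is the successive-day *change* in hatchery catch rate —
scaled but not centered, so "no change" stays exactly zero. Candidate
models (every admissible covariate subset) are ranked by
AICc = −2 logL + 2K + 2K(K+1)/(n−K−1); a variable whose summed Akaike
weight reaches 0.9 is flagged "important". Details, assumptions and
limitations: [docs/methods.md](docs/methods.md).

## Worked example

The numbered drivers under `analysis/` run the demonstration study end to
end (each regenerates what it needs; raw tables go under `scratch/`,
summaries under `results/`):

```bash
python analysis/01_simulate_dataset.py   # 8 seasons, known truth
python analysis/02_build_panels.py       # transforms + interpolation report
python analysis/03_fit_and_select.py     # selection, importance, diagnostics
python analysis/04_sensitivity.py        # unmarked-fish robustness checks
python analysis/05_calibration_studies.py
```

`03_fit_and_select.py` prints:

```
candidates fitted: 32 (variance structure: shared)
  collinear pair ['temp_anomaly', 'season'] (r=-0.60) resolved by single-covariate AICc
best model: hatchery_diff+temp_diff+flow_diff+season
  hatchery_diff  +0.138  (95% CI +0.126 to +0.151)
  temp_diff      +0.024  (95% CI +0.009 to +0.039)
  flow_diff      +0.059  (95% CI +0.043 to +0.075)
  season         +0.084  (95% CI +0.076 to +0.092)
relative variable importance (>= 0.9 flagged *):
  hatchery_diff  1.000 *
  season         1.000 *
  flow_diff      1.000 *
  temp_diff      0.979 *
  flow_anomaly   0.370
```

Read: the social covariate is in the best model, its effect is positive
with a CI excluding zero, and its importance is 1.0 — the three criteria
for a pied-piper signal — while a temperature/season collinearity was
caught and resolved first. Coefficients are per scaled-covariate unit on
the standardized log scale: +0.138 means a one-SD day-to-day increase in
hatchery catch rate raises the expected wild log catch rate by 0.138
chain-SDs that day, after the environmental effects. (The demo's generating
truth put the hatchery effect at 0.3 on this scale before per-chain
standardization of the response; detection, sign and ranking are the
targets here, and the coefficient-scale recovery experiments live in
`analysis/05` and the acceptance script.)

The same machinery is available programmatically
(`piedpiper.generate_dataset`, `build_panels`, `fit_mle`, `rank_models`,
`mislabeling_sensitivity`, `run_pipeline`) and as a CLI
(`piedpiper simulate | transform | fit | run | sensitivity`).

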