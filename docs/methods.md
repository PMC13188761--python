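# Methods

## The question and the model

Juvenile salmon (smolts) migrating downstream are counted daily at river
traps, separated into wild and hatchery-origin fish. Hatcheries release tens
of thousands of smolts in short pulses; the "pied-piper" hypothesis holds
that these pulses socially stimulate co-occurring wild smolts to migrate.
The statistical question is whether day-to-day *increases* in hatchery
catches predict increases in wild catches after accounting for environmental
drivers (flow, temperature, time of season) that could move both groups
independently.

Each (year × period) series of wild catches is one *chain*. With
`y_t` the standardized log catch rate of wild smolts and `c_t` the vector of
standardized covariates, the model is a multivariate autoregressive
state-space (MARSS) pair

    observation:  y_t = x_t + v_t,          v_t ~ N(0, r)
    process:      x_t = x_{t-1} + B c_t + w_t,  w_t ~ N(0, q)

— a log-scale random walk for the latent migration intensity `x_t`, driven
by covariate effects `B`, observed with noise. Chains are independent
(diagonal Q and R) but share parameters:

* environmental coefficients are tied across **all** chains (years and
  periods);
* the hatchery coefficient may optionally take separate day/night values
  (visual social cues should matter more in daylight);
* the process variance is either one shared scalar or a (q_day, q_night)
  pair — chosen once by AICc before model selection;
* the observation variance r is a single scalar.

Missing responses (trap suspensions) are marginalized exactly by the Kalman
filter (prediction-only steps); missing **covariate** values are not allowed
and are linearly interpolated beforehand.

## Data transforms

* **CPUE**: counts divided by trap effort hours per deployment. A day with
  no deployment is missing, never zero.
* **Response**: z-score of log(CPUE + 1), per chain, over the analysis
  window's non-missing days. Sample (n−1) standard deviations are used
  throughout, so a 3-point log series (0, 1, 2) standardizes to (−1, 0, 1).
* **Hatchery difference** (the social covariate): successive-day change in
  hatchery CPUE, divided by its SD but *not* centered, so "no change in
  hatchery fish" stays exactly zero. Its first element is missing by
  construction; transforms run over the full season and are then clipped to
  the analysis window, so the window's first day uses real pre-window data.
* **Anomalies** (flow, temperature): value minus the trailing mean of the 32
  days *strictly before* the current day, then z-scored. The trailing window
  excludes the current day.
* **Differences** (flow, temperature): day-to-day change, SD-scaled only.
* **Season**: (median migration day − day of year), SD-scaled only; positive
  before the median day of migration, zero on it, negative after. The median
  day is the first day on which half of the year's wild catch (pooled over
  periods, within the analysis window) has passed. Under the process model a
  positive season coefficient alone produces a bell-shaped count series.
* **Gap filling**: interior covariate gaps are filled linearly; leading and
  trailing gaps by nearest-value extension. The fraction filled is reported
  per covariate per chain. Responses are never filled.
* **Collinearity screen**: any covariate pair whose |Pearson r| rounds
  (half-up) to ≥ 0.5 at one decimal may not enter a model together; the pair
  member whose single-covariate model has the lower AICc survives, and a tie
  within 2 AICc units keeps both members as alternative branches of the
  candidate set.

All standardization is per chain over the analysis window only. Scaled
series carry their (mean, SD) as metadata and re-scaling one is rejected —
accidental double standardization is a silent-corruption hazard in this kind
of pipeline.

## Estimation

The exact Gaussian marginal likelihood is computed by a missing-aware
scalar Kalman filter per chain and summed over chains (a numba-compiled
kernel when available; a pure-numpy twin, cross-checked in the tests, is
the reference). Maximization is quasi-Newton (L-BFGS-B) over
(B, log q, log r); log-variances enforce positivity. The first start is a
method-of-moments initializer — OLS of response increments on the
covariates, with (q, r) from the variance and lag-1 autocovariance of the
residual increments (for increments, cov(e_t, e_{t+1}) = −r) — and later
starts are jittered. Starts stop early once the two best optima agree to a
relative 1e-6 in log-likelihood, which also defines convergence; up to five
starts are tried.

The initial state of each chain is fixed at its first observed response
with diffuse prior variance V0 = 5 (the response is standardized, so 5 is
far above the data variance), and is not counted as a parameter. The
alternative convention — estimate each x0, count it in K — is available via
`FitOptions(estimate_x0=True)`. The observation variance can be held fixed
(`fix_r`) for profile-style checks.

K counts coefficient slots plus variance parameters (q or q_day + q_night,
plus r). The effective sample size for AICc,

    AICc = −2 logL + 2K + 2K(K+1)/(n_eff − K − 1),

is the number of non-missing response values across chains. Autocorrelation
makes this an optimistic n; AICc's small-sample correction is the only
adjustment applied, and that caveat is inherited by anything downstream of
the model ranking.

Standard errors come from the inverse numerical Hessian (central
differences) of the negative log-likelihood at the optimum; variance SEs are
delta-method transforms from the log scale. 95% CIs are Wald (± 1.96 SE); a
coefficient is "significant" when its CI excludes zero. A singular observed
information matrix (for example, a zero-variance covariate) leaves SEs
unavailable and the fit flagged rather than inventing numbers.

Residual diagnostics use the standardized one-step prediction errors:
per-chain ACF with ±1.96/√n bands, Ljung–Box per chain plus a combined
χ² over chains, normal QQ points, and fitted-vs-residual pairs. Under the
true model the per-chain Ljung–Box p-values are uniform (verified by
simulation in the tests).

## Model selection and importance

Candidates are every subset of the admissible covariates (including the
empty random walk) that respects the collinearity exclusions. Ranking uses
AICc; Akaike weights are exp(−ΔAICc/2) normalized over the converged
candidate set; models with ΔAICc < 2 form the equal-support set.
Non-converged candidates are excluded from the weight normalization and
listed, never silently weighted zero. A variable's relative importance is
the summed weight of candidate models containing it; importance ≥ 0.9 flags
it "important". The variance-structure comparison and the pair-resolution
fits are pre-selection steps and are not part of the importance summation.
A split hatchery coefficient still counts as one variable.

## Sensitivity analyses

Unmarked hatchery fish are counted as wild at the trap, which could
manufacture an apparent social effect. Two probes:

* **Release correlation** — for each release, the day of peak hatchery catch
  within 10 days is paired with the wild count that day and with the
  estimated number of unmarked fish in the release (n_released × unmarked
  fraction); a strong Pearson correlation would indicate contamination. A
  leave-one-out table exposes single-release dominance.
* **Mislabeling sensitivity** — known (marked) hatchery fish are relabeled
  as wild by binomial thinning of each record's count at rates ρ starting
  at 0, panels are rebuilt and the best model refitted at each rate. The
  ρ = 0 point reproduces the baseline fit exactly (same data, same seeded
  optimizer). The apparent hatchery effect is regressed on ρ by ordinary
  least squares (the minimal functional form) and projected backward to
  −(assumed baseline unmarked fraction), estimating the effect in a
  fully-corrected dataset. The baseline fraction is a config input, never
  hard-coded; hatchery programs typically report under 5% unmarked.

A leave-one-year-out refit reports coefficient deltas against the full fit
in units of the full fit's SEs.

## The synthetic-data generator

The generator emulates the statistical structure the model assumes — not
fish physiology (no readiness/refractory dynamics, no individual behavior):

* **Environment**: temperature is a seasonal sinusoid plus stationary AR(1)
  noise (φ = 0.7, SD 0.5 °C); flow is a declining spring-freshet
  exponential trend plus Poisson-arriving spates with exponentially
  decaying magnitude and AR(1) noise. With noise amplitudes zero both
  collapse to their deterministic skeletons.
* **Hatchery releases**: each release spreads over subsequent days through a
  discretized log-normal travel-time kernel (median 3 d, spread 2 d; a
  unimodal right-skewed day lag reproduces the multi-day arrival pulses in
  real trap series), arrivals are thinned binomially by the trap capture
  probability (0.02 by default — trap efficiency is a free parameter, not an
  asserted value), split 80/20 night/day when both periods run, and split
  marked/unmarked by the release's unmarked fraction (default 5%).
  Unmarked fish are emitted as their own origin class; the transforms layer
  pools them into the observed wild series, mirroring what a trap crew sees.
* **Wild process**: the latent log(CPUE+1) starts at `x0_log` and follows
  the process equation, with the true coefficients applied to covariates
  scaled exactly as the estimator scales them (the generator calls the same
  transform code). Observed log response adds N(0, r) noise; counts are
  CPUE × effort rounded half-up (deterministic rounding keeps outputs
  byte-reproducible). Effort is mean ± 1 h uniform jitter, floored at 6 h.
  The generator's season covariate is anchored at the nominal window
  midpoint; the estimator re-derives the realized median day from the
  counts, and with a positive season effect the two coincide to within a
  couple of days.
* **Suspensions**: each day in the 10 days after a release is removed with
  probability 0.15 — whole days, all origins and both periods, since a
  physical trap suspension takes out the trap, not one shift.

Shipped study conditions: 15 night-only seasons of 120 days with an 80-day
analysis window (days 41–120); two releases per season (100k at day 55, 60k
at day 75); truth B = (hatchery 0.3, flow difference 0.15, season 0.2) on
the standardized scale with q = 0.05, r = 0.1.

### What the generator does and does not show

The per-chain z-scoring of the response means count-level simulation cannot
pin coefficients exactly: standardizing by each chain's *realized* sample SD
rescales the effective coefficients by ~1/SD, and a season effect of 0.2
integrates to a tall bell whose realized SD is well above 1. Count-level
data are therefore used where the question is *detection* (does selection
find the social covariate? does mislabeling create a spurious one?), while
parameter-recovery and coverage experiments simulate the response directly
from the observation/process equations over the same realistically-built
covariates — the truth then lives on the exact scale the estimator fits on,
and fitted coefficients are directly comparable to it. For the same reason
the generator's default season effect produces seasonal peak counts larger
than a typical real trap's; this affects nothing statistical, since the
estimator standardizes per chain.

Other features of real data the generator does not emulate: observation
error is homoscedastic on the log scale (real counting error is worse at
the pulse peaks), environment and releases are independent across years
(real hatcheries time releases to match wild migration, the very confound
the covariates are meant to absorb), and there is no fry/parr bimodality —
the analysis window is assumed already clipped to a single migration mode.
Passing tests therefore validate the machinery and its calibration under
the model's assumptions, not the biological conclusions on any real river.

## Validation experiments (experiments.py)

* **Likelihood oracle**: on randomized short chains with missing values the
  filter log-likelihood equals the brute-force joint multivariate-normal
  log-density (mean m0 + cumsum(u), covariance V0 + q·min(t,s) + r·I) to
  better than 1e-8.
* **Recovery**: 50 replicates at 15 chains × 80 days; coefficient bias
  under 0.05 and 95% CI coverage within Monte-Carlo range of nominal.
* **Importance calibration**: over the 16-model enumeration of 4 covariates,
  the hatchery covariate reaches importance ≥ 0.9 essentially always when
  its true effect is 0.3 and almost never when it is 0.
* **Variance structure**: (q_day, q_night) = (0.01, 0.5) is detected as
  unequal; equal truth mostly keeps the simpler shared structure (AICc's
  parsimony penalty).
* **Mislabeling**: with zero true social effect, injected mislabeling
  produces a positive effect-vs-rate slope, because mislabeled fish enter
  the wild series exactly during hatchery pulses.

`scripts/acceptance.py` reruns all of these at full size from scratch.

## Numerical choices and edge cases

* Natural logarithms throughout; coefficients are per scaled-covariate unit
  on the natural-log scale.
* CPUE is computed first, then log(CPUE + 1) — the "+1" guards the zero
  catches and is applied to the rate, keeping the effort correction inside
  the transform.
* Chains with fewer than 3 observed days, zero response variance, or no
  catch at all (median day undefined) are dropped with a report entry.
* A zero-variance covariate becomes an all-zero column with a warning; its
  coefficient is inestimable and the Hessian path flags SEs unavailable.
* q = r = 0 against non-degenerate data yields −∞ log-likelihood, not a
  crash; optimizers work on log-variances and never land there exactly.
* Rounding in the collinearity screen is half-up (not banker's), so the
  0.45 → 0.5 boundary is deterministic.
* Chains of unequal length are padded with missing observations and zero
  drift, which provably leaves the likelihood unchanged.

## Problem sizes

Tests and the acceptance script run the simulation studies at 10–50
replicates with 15 chains × 80 days (selection arms: 25 replicates × 16
candidate models), sizes at which every calibration quantity is stable; the
analysis drivers use an 8-season demo. Everything is deterministic given
the seeds in the scripts.
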