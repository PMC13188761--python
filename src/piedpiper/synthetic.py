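"""Synthetic multi-year trap datasets with known ground truth.

Emulates the statistical structure the state-space analysis assumes: a
log-scale random-walk wild-smolt process with covariate effects and Gaussian
observation noise, pulsed hatchery releases arriving at the trap through a
right-skewed travel-time kernel, seasonally varying flow and temperature,
effort-hour variation, and post-release trap suspensions (missing data).

Two entry points matter:

``generate_dataset``
    the full count-level pipeline: integer trap records, gauge series, truth
    bundle and latent states, written as delimited text files.
``make_model_panels``
    chains with covariates built by the transforms module from the same
    synthetic environment/hatchery series, but with the response simulated
    directly from the observation/process equations. This is the workhorse
    for parameter-recovery and selection-calibration experiments, where the
    truth must live on the same standardized scale the estimator fits on.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import transforms
from .transforms import ChainKey, ChainPanel, CovariateSpec, DEFAULT_COVARIATES

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_environment",
    "simulate_hatchery_counts",
    "simulate_wild_counts",
    "inject_missingness",
    "generate_dataset",
    "make_model_panels",
    "ar1",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters and structure of a synthetic study.

    Defaults are the shipped study conditions: 15 single-period (night)
    seasons of 120 days with an 80-day analysis window (days 41-120), two
    pulsed releases per season with 5% unmarked fish, coefficient truth
    (hatchery 0.3, flow difference 0.15, season 0.2) on the standardized
    scale, process/observation variances 0.05/0.1, and occasional trap
    suspensions after releases.
    """

    n_years: int = 15
    season_days: int = 120
    first_day: int = 41
    last_day: int = 120
    periods: tuple[str, ...] = ("night",)
    true_B: dict = field(
        default_factory=lambda: {"hatchery_diff": 0.3, "flow_diff": 0.15, "season": 0.2}
    )
    q_process: float | dict = 0.05  # scalar or {'day': .., 'night': ..}
    r_obs: float = 0.1
    # releases: (day_of_year, fish released, unmarked fraction)
    release_schedule: tuple = ((55, 100_000, 0.05), (75, 60_000, 0.05))
    mean_travel_days: float = 3.0
    travel_spread_days: float = 2.0
    capture_prob: float = 0.02  # trap efficiency (free parameter, not asserted)
    night_fraction: float = 0.8  # share of arrivals during the night period
    effort_hours_mean: float = 12.0
    effort_jitter_hours: float = 1.0
    effort_min_hours: float = 6.0
    suspension_prob: float = 0.15
    x0_log: float = 0.5  # log(CPUE+1) of wild fish at the window start
    # environment
    temp_mean: float = 9.0
    temp_amplitude: float = 6.0
    temp_phase_day: float = 100.0
    temp_ar_phi: float = 0.7
    temp_ar_sd: float = 0.5
    flow_base: float = 300.0
    flow_floor: float = 60.0
    flow_freshet_decay: float = 80.0
    spate_rate: float = 0.04  # spate events per day
    spate_magnitude: float = 150.0
    spate_decay_days: float = 3.0
    flow_ar_phi: float = 0.7
    flow_ar_sd: float = 10.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.season_days <= 33:
            raise ValueError("season_days must exceed 33 (anomaly window must fit)")
        if not (1 <= self.first_day < self.last_day <= self.season_days):
            raise ValueError("analysis window must lie inside the season")
        for q in self.q_values().values():
            if q < 0:
                raise ValueError("process variance must be non-negative")
        if self.r_obs < 0:
            raise ValueError("observation variance must be non-negative")
        for day, n_fish, unmarked in self.release_schedule:
            if n_fish < 0:
                raise ValueError("release size must be non-negative")
            if not 0.0 <= unmarked <= 1.0:
                raise ValueError("unmarked fraction must lie in [0, 1]")
        for period in self.periods:
            if period not in transforms.PERIODS:
                raise ValueError(f"unknown period {period!r}")

    def q_values(self) -> dict[str, float]:
        if isinstance(self.q_process, dict):
            return {p: float(self.q_process[p]) for p in self.periods}
        return {p: float(self.q_process) for p in self.periods}

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["release_schedule"] = [list(r) for r in self.release_schedule]
        out["periods"] = list(self.periods)
        return out


@dataclass
class SyntheticDataset:
    trap: pd.DataFrame
    env: pd.DataFrame
    latent: pd.DataFrame
    truth: dict
    gap_log: list


def ar1(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) path with marginal standard deviation ``sd``."""
    x = np.empty(n)
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(max(1.0 - phi**2, 0.0))
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def simulate_environment(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Daily gauge series per year: sinusoidal temperature with AR(1) noise;
    flow as a declining spring-freshet trend plus exponentially decaying
    spates and AR(1) noise. Deterministic under the config seed."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    days = np.arange(1, config.season_days + 1)
    frames = []
    for year in range(1, config.n_years + 1):
        temp = config.temp_mean + config.temp_amplitude * np.sin(
            2.0 * np.pi * (days - config.temp_phase_day) / 365.25
        )
        temp = temp + ar1(len(days), config.temp_ar_phi, config.temp_ar_sd, rng)
        flow = config.flow_floor + config.flow_base * np.exp(
            -days / config.flow_freshet_decay
        )
        if config.spate_rate > 0:
            n_events = rng.poisson(config.spate_rate * len(days))
            event_days = rng.integers(1, config.season_days + 1, size=n_events)
            magnitudes = rng.exponential(config.spate_magnitude, size=n_events)
            for d0, mag in zip(event_days, magnitudes):
                lag = days - d0
                flow = flow + np.where(
                    lag >= 0, mag * np.exp(-lag / config.spate_decay_days), 0.0
                )
        flow = flow + ar1(len(days), config.flow_ar_phi, config.flow_ar_sd, rng)
        frames.append(
            pd.DataFrame(
                {"year": year, "day_of_year": days, "flow": flow, "temperature": temp}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _arrival_kernel(config: SyntheticConfig, max_lag: int = 40) -> np.ndarray:
    """Discretized log-normal release-to-trap travel time (right-skewed)."""
    sigma = max(config.travel_spread_days / config.mean_travel_days, 1e-3)
    dist = stats.lognorm(s=sigma, scale=config.mean_travel_days)
    edges = np.arange(max_lag + 1, dtype=float)
    mass = dist.cdf(edges[1:]) - dist.cdf(edges[:-1])
    total = mass.sum()
    if total <= 0:
        mass = np.zeros(max_lag)
        mass[min(int(round(config.mean_travel_days)), max_lag - 1)] = 1.0
        return mass
    return mass / total


def draw_effort(
    config: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Trap effort hours per (year, day, period): mean with uniform jitter,
    truncated below at the configured minimum."""
    rows = []
    for year in range(1, config.n_years + 1):
        for period in config.periods:
            hours = config.effort_hours_mean + rng.uniform(
                -config.effort_jitter_hours,
                config.effort_jitter_hours,
                size=config.season_days,
            )
            hours = np.maximum(hours, config.effort_min_hours)
            rows.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "day_of_year": np.arange(1, config.season_days + 1),
                        "period": period,
                        "effort_hours": hours,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_hatchery_counts(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    effort: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Trap records for hatchery fish from the pulsed release schedule.

    Each release spreads over subsequent days through the travel-time kernel
    (multinomial arrivals), is thinned binomially by the trap capture
    probability, split across periods, and split marked/unmarked by the
    release's unmarked fraction. An empty schedule yields all-zero counts.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    if effort is None:
        effort = draw_effort(config, rng)
    kernel = _arrival_kernel(config)
    n_days = config.season_days
    counts = {
        (p, origin): np.zeros((config.n_years, n_days), dtype=np.int64)
        for p in config.periods
        for origin in ("hatchery_marked", "hatchery_unmarked")
    }
    for year in range(1, config.n_years + 1):
        for day0, n_fish, unmarked_frac in config.release_schedule:
            if n_fish == 0:
                continue
            arrivals = rng.multinomial(int(n_fish), kernel)
            for lag, n_arrive in enumerate(arrivals):
                day = int(day0) + lag
                if n_arrive == 0 or day > n_days:
                    continue
                trapped = rng.binomial(n_arrive, config.capture_prob)
                if trapped == 0:
                    continue
                per_period = _split_periods(trapped, config, rng)
                for period, n_period in per_period.items():
                    n_unmarked = rng.binomial(n_period, unmarked_frac)
                    counts[(period, "hatchery_unmarked")][year - 1, day - 1] += n_unmarked
                    counts[(period, "hatchery_marked")][year - 1, day - 1] += (
                        n_period - n_unmarked
                    )
    rows = []
    days = np.arange(1, n_days + 1)
    for (period, origin), mat in counts.items():
        for year in range(1, config.n_years + 1):
            rows.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "day_of_year": days,
                        "period": period,
                        "origin": origin,
                        "count": mat[year - 1],
                    }
                )
            )
    records = pd.concat(rows, ignore_index=True)
    return records.merge(effort, on=["year", "day_of_year", "period"], how="left")


def _split_periods(n: int, config: SyntheticConfig, rng) -> dict[str, int]:
    if len(config.periods) == 1:
        return {config.periods[0]: n}
    n_night = rng.binomial(n, config.night_fraction)
    return {"night": n_night, "day": n - n_night}


# ---------------------------------------------------------------------------
# covariates and the wild-fish process
# ---------------------------------------------------------------------------


def _chain_covariates(
    env_year: pd.DataFrame,
    hatchery_cpue: np.ndarray,
    config: SyntheticConfig,
    covariates: tuple[CovariateSpec, ...],
) -> dict[str, np.ndarray]:
    """Scaled covariates for one chain, using the estimator's conventions.

    Transforms run over the full season and are clipped to the analysis
    window before standardization, exactly as ``transforms.build_panels``
    does, so the ground-truth coefficients live on the estimator's scale.
    The season covariate is anchored at the nominal window midpoint (the
    estimator re-derives the realized median migration day from the counts).
    """
    days = env_year["day_of_year"].to_numpy()
    window = (days >= config.first_day) & (days <= config.last_day)
    midpoint = 0.5 * (config.first_day + config.last_day)
    out: dict[str, np.ndarray] = {}
    for spec in covariates:
        if spec.transform == "season":
            raw = midpoint - days.astype(float)
        else:
            source = (
                hatchery_cpue
                if spec.source == "hatchery_cpue"
                else env_year[spec.source].to_numpy(dtype=float)
            )
            if spec.transform == "anomaly":
                raw = transforms.trailing_anomaly(source, spec.window_days)
            elif spec.transform == "difference":
                raw = transforms.lag_difference(source)
            else:
                raw = source
        clipped = raw[window]
        scaled, _ = transforms.scale_covariate(clipped, center=spec.center)
        out[spec.name] = np.asarray(scaled)
    return out


def _hatchery_cpue_grid(
    hatchery: pd.DataFrame, config: SyntheticConfig
) -> dict[tuple[int, str], np.ndarray]:
    """Marked-hatchery CPUE per chain over the full season grid (the social
    cue the estimator will reconstruct)."""
    marked = hatchery[hatchery["origin"] == "hatchery_marked"]
    out = {}
    for year in range(1, config.n_years + 1):
        for period in config.periods:
            sub = marked[(marked["year"] == year) & (marked["period"] == period)]
            grid = (
                sub.set_index("day_of_year")
                .reindex(range(1, config.season_days + 1))
                .fillna({"count": 0.0, "effort_hours": config.effort_hours_mean})
            )
            out[(year, period)] = (
                grid["count"].to_numpy(dtype=float)
                / grid["effort_hours"].to_numpy(dtype=float)
            )
    return out


def simulate_wild_counts(
    env: pd.DataFrame,
    hatchery: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    effort: pd.DataFrame | None = None,
    covariates: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wild trap records from the latent log-scale random walk.

    The latent state starts at ``x0_log`` (log(CPUE+1) units) at the window
    start and evolves with drift ``sum_k B_k c_kt`` over the scaled
    covariates plus process noise; observed log response adds observation
    noise; counts are CPUE times effort, rounded half-up. Returns the wild
    records and the latent-state table so estimates can be scored.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    if effort is None:
        effort = draw_effort(config, rng)
    h_grid = _hatchery_cpue_grid(hatchery, config)
    used = tuple(c for c in covariates if c.name in config.true_B)
    q = config.q_values()
    record_rows, latent_rows = [], []
    for year, env_year in env.groupby("year"):
        env_year = env_year.sort_values("day_of_year")
        days = env_year["day_of_year"].to_numpy()
        window = (days >= config.first_day) & (days <= config.last_day)
        w_days = days[window]
        for period in config.periods:
            cov = _chain_covariates(env_year, h_grid[(year, period)], config, used)
            u = np.zeros(int(window.sum()))
            for name, values in cov.items():
                u = u + config.true_B[name] * values
            w = rng.normal(0.0, np.sqrt(q[period]), size=len(u))
            x = config.x0_log + np.cumsum(u + w)
            obs_log = x + rng.normal(0.0, np.sqrt(config.r_obs), size=len(x))
            cpue = np.maximum(np.expm1(obs_log), 0.0)
            eff = (
                effort[
                    (effort["year"] == year) & (effort["period"] == period)
                ]
                .set_index("day_of_year")["effort_hours"]
                .reindex(w_days)
                .to_numpy()
            )
            counts = np.floor(cpue * eff + 0.5).astype(np.int64)
            record_rows.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "day_of_year": w_days,
                        "period": period,
                        "origin": "wild",
                        "count": counts,
                        "effort_hours": eff,
                    }
                )
            )
            latent_rows.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "day_of_year": w_days,
                        "period": period,
                        "x_log": x,
                        "drift": u,
                        "obs_log": obs_log,
                    }
                )
            )
    return (
        pd.concat(record_rows, ignore_index=True),
        pd.concat(latent_rows, ignore_index=True),
    )


def inject_missingness(
    records: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Remove post-release trap-suspension days.

    Each day within the 10 days after a release is suspended independently
    with probability ``suspension_prob``; a suspended day removes every
    record of that (year, day) — the physical trap is out for all origins
    and periods. Returns the thinned records and a gap log.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    if config.suspension_prob == 0.0 or not len(config.release_schedule):
        return records.copy(), []
    eligible = sorted(
        {
            day
            for day0, _, _ in config.release_schedule
            for day in range(int(day0) + 1, int(day0) + 11)
            if day <= config.season_days
        }
    )
    gap_log = []
    drop_keys = set()
    for year in sorted(records["year"].unique()):
        for day in eligible:
            if rng.random() < config.suspension_prob:
                drop_keys.add((int(year), int(day)))
                gap_log.append({"year": int(year), "day_of_year": int(day)})
    if not drop_keys:
        return records.copy(), gap_log
    keys = list(zip(records["year"].astype(int), records["day_of_year"].astype(int)))
    keep = np.array([k not in drop_keys for k in keys])
    return records[keep].reset_index(drop=True), gap_log


def generate_dataset(
    config: SyntheticConfig, outdir: str | Path | None = None
) -> SyntheticDataset:
    """Compose environment, hatchery, wild and missingness into one dataset.

    With ``outdir``, writes ``trap.csv``, ``env.csv``, ``latent.csv`` and
    ``truth.json``; the files round-trip bit-identically through the package
    readers. Deterministic (byte-identical) under the config seed.
    """
    rng = np.random.default_rng(config.rng_seed)
    env_rng, eff_rng, hat_rng, wild_rng, gap_rng = rng.spawn(5)
    env = simulate_environment(config, env_rng)
    effort = draw_effort(config, eff_rng)
    hatchery = simulate_hatchery_counts(config, hat_rng, effort=effort)
    wild, latent = simulate_wild_counts(env, hatchery, config, wild_rng, effort=effort)
    trap = pd.concat([wild, hatchery], ignore_index=True).sort_values(
        ["year", "day_of_year", "period", "origin"], ignore_index=True
    )
    trap, gap_log = inject_missingness(trap, config, gap_rng)
    truth = {
        "true_B": dict(config.true_B),
        "q_process": config.q_values(),
        "r_obs": config.r_obs,
        "rng_seed": config.rng_seed,
        "config": config.to_dict(),
        "gap_log": gap_log,
    }
    dataset = SyntheticDataset(
        trap=trap, env=env, latent=latent, truth=truth, gap_log=gap_log
    )
    if outdir is not None:
        write_dataset(dataset, outdir)
    return dataset


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        dataset.trap.to_csv(outdir / "trap.csv", index=False)
        dataset.env.to_csv(outdir / "env.csv", index=False)
        dataset.latent.to_csv(outdir / "latent.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(dataset.truth, indent=2))
    except OSError as err:
        raise OSError(f"failed writing synthetic dataset under {outdir}: {err}") from err


# ---------------------------------------------------------------------------
# model-scale panels for recovery/calibration experiments
# ---------------------------------------------------------------------------


def make_model_panels(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    covariate_names: tuple[str, ...] | None = None,
) -> tuple[list[ChainPanel], dict]:
    """Chains with realistic covariates and a response drawn from the model.

    Covariates come from a fresh synthetic environment and hatchery series,
    transformed and standardized with the estimator's conventions; the
    response is then simulated directly from the observation/process
    equations with the config's true parameters, so it already lives on the
    standardized scale and fitted coefficients are directly comparable to
    ``true_B``. Returns the panels plus the truth bundle (latent states).
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    env_rng, hat_rng, proc_rng = rng.spawn(3)
    env = simulate_environment(config, env_rng)
    hatchery = simulate_hatchery_counts(config, hat_rng)
    h_grid = _hatchery_cpue_grid(hatchery, config)
    if covariate_names is None:
        names = tuple(config.true_B)
    else:
        names = covariate_names
    specs = tuple(c for c in DEFAULT_COVARIATES if c.name in names)
    missing = set(names) - {c.name for c in specs}
    if missing:
        raise ValueError(f"unknown covariates: {sorted(missing)}")
    q = config.q_values()
    panels: list[ChainPanel] = []
    latent: dict[ChainKey, np.ndarray] = {}
    for year, env_year in env.groupby("year"):
        env_year = env_year.sort_values("day_of_year")
        days = env_year["day_of_year"].to_numpy()
        window = (days >= config.first_day) & (days <= config.last_day)
        for period in config.periods:
            cov = _chain_covariates(env_year, h_grid[(year, period)], config, specs)
            n = int(window.sum())
            u = np.zeros(n)
            for name, values in cov.items():
                u = u + config.true_B.get(name, 0.0) * values
            w = proc_rng.normal(0.0, np.sqrt(q[period]), size=n)
            x = np.cumsum(u + w)
            y = x + proc_rng.normal(0.0, np.sqrt(config.r_obs), size=n)
            key = ChainKey(int(year), period)
            latent[key] = x
            panels.append(
                ChainPanel(
                    key=key,
                    day_of_year=days[window],
                    response=y,
                    covariates=cov,
                    scaling={},
                )
            )
    truth = {
        "true_B": dict(config.true_B),
        "q_process": q,
        "r_obs": config.r_obs,
        "latent": latent,
    }
    return panels, truth
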