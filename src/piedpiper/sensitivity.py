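"""Robustness checks for the unmarked-hatchery-fish confound.

Unmarked hatchery fish are counted as wild at the trap. Two procedures probe
whether that misidentification could manufacture an apparent social effect:

* ``unmarked_release_correlation`` — correlate the estimated number of
  unmarked fish in each release with the wild count on the peak hatchery day
  within 10 days of the release (plus a leave-one-out table exposing
  single-release dominance).
* ``mislabeling_sensitivity`` — deliberately relabel known hatchery fish as
  wild at increasing rates, refit, and use the rate of increase of the
  apparent effect to project backward to a fully-corrected dataset.

``exclude_year_refit`` drops one year and refits, for leave-one-year-out
stability checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ssm import FitOptions, FitResult, ModelSpec, fit_mle
from .transforms import ChainPanel, CovariateSpec, DEFAULT_COVARIATES, build_panels

__all__ = [
    "ReleaseEvent",
    "CorrelationResult",
    "MislabelResult",
    "unmarked_release_correlation",
    "relabel_hatchery",
    "mislabeling_sensitivity",
    "fit_projection",
    "exclude_year_refit",
]


@dataclass(frozen=True)
class ReleaseEvent:
    year: int
    day_of_year: int
    n_released: int
    unmarked_fraction: float

    def __post_init__(self):
        if self.n_released < 0:
            raise ValueError("release size must be non-negative")
        if not 0.0 <= self.unmarked_fraction <= 1.0:
            raise ValueError("unmarked fraction must lie in [0, 1]")


@dataclass
class CorrelationResult:
    r: float  # NaN when undefined (< 3 usable pairs)
    pairs: pd.DataFrame
    dropped: list[dict]
    leave_one_out: pd.DataFrame


def unmarked_release_correlation(
    records: pd.DataFrame,
    releases: list[ReleaseEvent],
    window_days: int = 10,
) -> CorrelationResult:
    """Pearson correlation of unmarked-released numbers against the wild count
    on the peak marked-hatchery day within ``window_days`` of each release.

    Counts are pooled across periods per day. Releases whose window holds no
    trap data are dropped and reported. Fewer than three usable pairs leave
    the correlation undefined (NaN). The leave-one-out table recomputes the
    correlation with each release removed, exposing single-release dominance.
    """
    daily = (
        records.assign(
            group=np.where(
                records["origin"] == "hatchery_marked", "hatchery", "wild_observed"
            )
        )
        .groupby(["year", "day_of_year", "group"])["count"]
        .sum()
        .unstack("group")
        .reindex(columns=["hatchery", "wild_observed"])
    )
    pairs, dropped = [], []
    for event in releases:
        lo, hi = event.day_of_year, event.day_of_year + window_days
        try:
            window = daily.loc[(event.year, slice(lo, hi)), :]
        except KeyError:
            window = pd.DataFrame()
        window = window.dropna(how="all")
        if window.empty or window["hatchery"].isna().all():
            dropped.append(
                {"year": event.year, "day_of_year": event.day_of_year,
                 "reason": "no trap data in window"}
            )
            continue
        peak_day = int(window["hatchery"].idxmax()[1])
        wild = window.loc[(event.year, peak_day), "wild_observed"]
        pairs.append(
            {
                "year": event.year,
                "release_day": event.day_of_year,
                "peak_hatchery_day": peak_day,
                "unmarked_released": event.n_released * event.unmarked_fraction,
                "wild_count": float(wild) if np.isfinite(wild) else 0.0,
            }
        )
    pairs = pd.DataFrame(
        pairs,
        columns=[
            "year", "release_day", "peak_hatchery_day",
            "unmarked_released", "wild_count",
        ],
    )
    r = _pearson(pairs["unmarked_released"], pairs["wild_count"])
    loo_rows = []
    for i in pairs.index:
        rest = pairs.drop(index=i)
        loo_rows.append(
            {
                "left_out_year": pairs.loc[i, "year"],
                "left_out_release_day": pairs.loc[i, "release_day"],
                "r": _pearson(rest["unmarked_released"], rest["wild_count"]),
            }
        )
    return CorrelationResult(
        r=r,
        pairs=pairs,
        dropped=dropped,
        leave_one_out=pd.DataFrame(
            loo_rows, columns=["left_out_year", "left_out_release_day", "r"]
        ),
    )


def _pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# mislabeling sensitivity
# ---------------------------------------------------------------------------


@dataclass
class MislabelResult:
    rates: np.ndarray
    effects: np.ndarray  # NaN where the refit diverged
    slope: float
    intercept: float
    projected_effect_at_zero: float
    baseline_fraction: float
    fits: list[FitResult] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.tolist(),
            "effects": self.effects.tolist(),
            "slope": self.slope,
            "intercept": self.intercept,
            "projected_effect_at_zero": self.projected_effect_at_zero,
            "baseline_fraction": self.baseline_fraction,
        }


def relabel_hatchery(
    records: pd.DataFrame, rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Move a Binomial(count, rate) share of each marked-hatchery record's
    count into the wild count of the same (year, day, period).

    Binomial thinning keeps counts integer and is seedable; rate 0 is an
    exact identity.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mislabel rate must lie in [0, 1]")
    out = records.copy()
    if rate == 0.0:
        return out
    marked = out["origin"] == "hatchery_marked"
    moved = rng.binomial(out.loc[marked, "count"].to_numpy(dtype=np.int64), rate)
    out.loc[marked, "count"] = out.loc[marked, "count"].to_numpy() - moved
    extra = out.loc[marked, ["year", "day_of_year", "period", "effort_hours"]].copy()
    extra["count"] = moved
    extra["origin"] = "wild"
    extra = extra[extra["count"] > 0]
    out = pd.concat([out, extra], ignore_index=True)
    return (
        out.groupby(["year", "day_of_year", "period", "origin"], as_index=False)
        .agg(count=("count", "sum"), effort_hours=("effort_hours", "first"))
        .sort_values(["year", "day_of_year", "period", "origin"], ignore_index=True)
    )


def fit_projection(
    rates, effects, baseline_fraction: float = 0.0
) -> tuple[float, float, float]:
    """Least-squares line through (rate, effect); the backward projection
    evaluates it at -baseline_fraction (undoing the assumed pre-existing
    mislabeling). Returns (slope, intercept, projected effect)."""
    rates = np.asarray(rates, dtype=float)
    effects = np.asarray(effects, dtype=float)
    ok = np.isfinite(effects)
    if ok.sum() < 2:
        raise ValueError("need at least two converged rates for the projection")
    slope, intercept = np.polyfit(rates[ok], effects[ok], 1)
    projected = intercept - slope * baseline_fraction
    return float(slope), float(intercept), float(projected)


def mislabeling_sensitivity(
    trap: pd.DataFrame,
    env: pd.DataFrame,
    spec: ModelSpec,
    rates,
    first_day: int,
    last_day: int,
    covariates: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES,
    baseline_fraction: float = 0.0,
    seed: int = 0,
    options: FitOptions | None = None,
    effect_period: str = "night",
) -> MislabelResult:
    """Relabel known hatchery fish as wild at each rate, rebuild panels,
    refit, and project the hatchery effect back to a corrected dataset.

    Rates must start at 0 (the baseline fit, reproduced exactly). A diverged
    refit is flagged (NaN effect) and excluded from the projection line.
    """
    rates = np.asarray(list(rates), dtype=float)
    if rates[0] != 0.0:
        raise ValueError("rates must start at 0 (the baseline fit)")
    effects = np.full(len(rates), np.nan)
    fits: list[FitResult] = []
    for i, rate in enumerate(rates):
        rng = np.random.default_rng([seed, i])
        relabeled = relabel_hatchery(trap, float(rate), rng)
        panels, _ = build_panels(
            relabeled, env, first_day, last_day, covariates=covariates
        )
        fit = fit_mle(spec, panels, options=options)
        fits.append(fit)
        if fit.converged:
            effects[i] = fit.hatchery_effect(effect_period)
    slope, intercept, projected = fit_projection(rates, effects, baseline_fraction)
    return MislabelResult(
        rates=rates,
        effects=effects,
        slope=slope,
        intercept=intercept,
        projected_effect_at_zero=projected,
        baseline_fraction=baseline_fraction,
        fits=fits,
    )


def exclude_year_refit(
    panels: list[ChainPanel],
    spec: ModelSpec,
    year: int,
    options: FitOptions | None = None,
) -> dict:
    """Drop all chains of one year, refit, and report coefficient deltas."""
    years = {p.key.year for p in panels}
    if years == {year}:
        raise ValueError("dropping the only year would leave no chains")
    if len(years) < 2:
        raise ValueError("need more than one year for a leave-one-out refit")
    kept = [p for p in panels if p.key.year != year]
    full = fit_mle(spec, panels, options=options)
    reduced = fit_mle(spec, kept, options=options)
    deltas = {
        name: reduced.params.B[name] - full.params.B[name] for name in full.params.B
    }
    return {
        "year_dropped": year,
        "full": full,
        "reduced": reduced,
        "coefficient_deltas": deltas,
        "full_se": dict(full.se),
        "reduced_se": dict(reduced.se),
    }
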