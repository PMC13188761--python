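"""Response and covariate engineering for trap-count migration series.

Turns raw trap and gauge tables into the standardized series the state-space
model consumes: catch per unit effort (CPUE), log(+1) response z-scored per
chain, the hatchery-difference social covariate, trailing-window anomalies,
day-to-day differences, the season covariate anchored at the median migration
day, linear gap interpolation for covariates, and the pairwise collinearity
screen.

A *chain* is one (year, period) series: day and night counts of the same year
are modeled as independent series that share coefficients. All scaling is done
per chain over the analysis window, so coefficients are comparable across
chains and years.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ChainKey",
    "ChainPanel",
    "CovariateSpec",
    "ChainUnusableError",
    "AlreadyScaledError",
    "ScaledArray",
    "DEFAULT_COVARIATES",
    "compute_cpue",
    "log_scale_response",
    "hatchery_difference",
    "trailing_anomaly",
    "lag_difference",
    "median_migration_day",
    "season_covariate",
    "scale_covariate",
    "interpolate_gaps",
    "screen_collinearity",
    "round_half_up",
    "build_panels",
]

PERIODS = ("day", "night")
ORIGINS = ("wild", "hatchery_marked", "hatchery_unmarked")


class ChainKey(NamedTuple):
    year: int
    period: str


class ChainUnusableError(ValueError):
    """Raised when a (year, period) chain cannot enter the analysis."""


class AlreadyScaledError(ValueError):
    """Raised when a scaling transform is applied to an already-scaled series."""


class ScaledArray(np.ndarray):
    """ndarray carrying the (mean, sd) used to standardize it.

    The marker lets the pipeline detect and reject double scaling.
    """

    def __new__(cls, values, mean: float, sd: float):
        obj = np.asarray(values, dtype=float).view(cls)
        obj.scaling = (float(mean), float(sd))
        return obj

    def __array_finalize__(self, obj):
        if obj is not None:
            self.scaling = getattr(obj, "scaling", None)


def _check_not_scaled(values) -> np.ndarray:
    if isinstance(values, ScaledArray) or getattr(values, "scaling", None):
        raise AlreadyScaledError("series has already been scaled")
    return np.asarray(values, dtype=float)


def round_half_up(x, decimals: int = 0):
    """Round half away from zero (0.45 -> 0.5 at one decimal)."""
    factor = 10.0**decimals
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


@dataclass(frozen=True)
class CovariateSpec:
    """How one covariate is derived and standardized.

    transform:
        'anomaly'    value minus its trailing ``window_days`` mean, z-scored
        'difference' day-to-day change, divided by its SD only
        'season'     median migration day minus day of year, divided by SD only
        'raw'        the source series itself
    source:
        column of the daily chain table the transform reads
        ('temperature', 'flow', 'hatchery_cpue'); ignored for 'season'.
    """

    name: str
    transform: str
    source: str = ""
    window_days: int = 32
    predicted_sign: str = "unknown"

    @property
    def center(self) -> bool:
        # Anomalies are scaled and centered; differences and season are scaled
        # only so that "no change" / "median day" stay exactly at zero.
        return self.transform == "anomaly"

    def __post_init__(self):
        if self.transform not in ("anomaly", "difference", "season", "raw"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "anomaly" and self.window_days < 1:
            raise ValueError("anomaly requires window_days >= 1")


DEFAULT_COVARIATES: tuple[CovariateSpec, ...] = (
    CovariateSpec("hatchery_diff", "difference", "hatchery_cpue", predicted_sign="+"),
    CovariateSpec("temp_anomaly", "anomaly", "temperature", predicted_sign="+"),
    CovariateSpec("temp_diff", "difference", "temperature", predicted_sign="+"),
    CovariateSpec("flow_anomaly", "anomaly", "flow", predicted_sign="-"),
    CovariateSpec("flow_diff", "difference", "flow", predicted_sign="+"),
    CovariateSpec("season", "season", predicted_sign="+"),
)


@dataclass
class ChainPanel:
    """Aligned per-chain arrays the state-space model consumes.

    ``response`` is the z-scored log(CPUE + 1) of wild catches with NaN for
    missing trap days; ``covariates`` are gap-free standardized series.
    """

    key: ChainKey
    day_of_year: np.ndarray
    response: np.ndarray
    covariates: dict[str, np.ndarray]
    interpolation_report: dict[str, dict] = field(default_factory=dict)
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def missing_response_mask(self) -> np.ndarray:
        return ~np.isfinite(self.response)

    @property
    def n_obs(self) -> int:
        return int(np.isfinite(self.response).sum())

    def validate(self) -> None:
        n = len(self.day_of_year)
        if len(self.response) != n:
            raise ValueError("response length mismatch")
        for name, values in self.covariates.items():
            if len(values) != n:
                raise ValueError(f"covariate {name!r} length mismatch")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"covariate {name!r} contains missing values")


# ---------------------------------------------------------------------------
# elemental transforms
# ---------------------------------------------------------------------------


def compute_cpue(
    records: pd.DataFrame,
    day_range: tuple[int, int] | None = None,
    unmarked_as_wild: bool = True,
) -> pd.DataFrame:
    """Daily catch per unit effort per (year, period), wild and hatchery apart.

    Returns a frame with one row per (year, period, day_of_year) on the full
    day grid and columns ``wild_cpue``, ``hatchery_cpue``, ``wild_count``,
    ``effort_hours``. Days on which the trap did not fish are NaN (missing is
    not zero); days the trap fished but caught none of a group are 0.

    ``unmarked_as_wild`` mirrors field practice: unmarked hatchery fish cannot
    be told from wild fish at the trap, so their counts land in the wild
    series; the hatchery covariate uses marked fish only.
    """
    records = records.copy()
    bad = records["effort_hours"] <= 0
    if bad.any():
        warnings.warn(f"rejected {int(bad.sum())} records with non-positive effort")
        records = records[~bad]

    wild_origins = {"wild"}
    hatchery_origins = {"hatchery_marked"}
    (wild_origins if unmarked_as_wild else hatchery_origins).add("hatchery_unmarked")

    records["group"] = np.where(
        records["origin"].isin(list(wild_origins)), "wild", "hatchery"
    )
    grouped = (
        records.groupby(["year", "period", "day_of_year", "group"])
        .agg(count=("count", "sum"), effort_hours=("effort_hours", "first"))
        .reset_index()
    )
    wide = grouped.pivot_table(
        index=["year", "period", "day_of_year"],
        columns="group",
        values="count",
        aggfunc="sum",
    )
    # a fished day with no record for one group is an observed zero
    wide = wide.reindex(columns=["wild", "hatchery"]).fillna(0.0)
    effort = grouped.groupby(["year", "period", "day_of_year"])["effort_hours"].first()
    out = wide.join(effort)

    frames = []
    for (year, period), sub in out.groupby(level=["year", "period"]):
        days = sub.index.get_level_values("day_of_year")
        lo, hi = (int(days.min()), int(days.max())) if day_range is None else day_range
        grid = pd.MultiIndex.from_product(
            [[year], [period], range(lo, hi + 1)],
            names=["year", "period", "day_of_year"],
        )
        frames.append(sub.reindex(grid))
    out = pd.concat(frames)
    out["wild_cpue"] = out["wild"] / out["effort_hours"]
    out["hatchery_cpue"] = out["hatchery"] / out["effort_hours"]
    return (
        out.rename(columns={"wild": "wild_count", "hatchery": "hatchery_count"})
        .reset_index()
        .sort_values(["year", "period", "day_of_year"], ignore_index=True)
    )


def log_scale_response(cpue, min_obs: int = 3) -> tuple[ScaledArray, dict]:
    """z-score of log(CPUE + 1) over a chain's non-missing days.

    Raises :class:`ChainUnusableError` for chains with fewer than ``min_obs``
    observed days or zero variance (nothing to standardize against).
    """
    cpue = _check_not_scaled(cpue)
    if np.any(cpue[np.isfinite(cpue)] < 0):
        raise ValueError("CPUE must be non-negative")
    logged = np.log1p(cpue)
    obs = np.isfinite(logged)
    if obs.sum() < min_obs:
        raise ChainUnusableError(f"only {int(obs.sum())} observed days (< {min_obs})")
    mean = float(np.mean(logged[obs]))
    sd = float(np.std(logged[obs], ddof=1))
    if sd == 0.0:
        raise ChainUnusableError("constant response (zero standard deviation)")
    out = np.full_like(logged, np.nan)
    out[obs] = (logged[obs] - mean) / sd
    meta = {"mean": mean, "sd": sd, "n_obs": int(obs.sum())}
    return ScaledArray(out, mean, sd), meta


def lag_difference(series) -> np.ndarray:
    """Day-to-day change v_t - v_{t-1}; first element missing by construction."""
    series = np.asarray(series, dtype=float)
    out = np.full_like(series, np.nan)
    out[1:] = series[1:] - series[:-1]
    return out


def hatchery_difference(hatchery_cpue) -> tuple[ScaledArray, dict]:
    """The social covariate: successive-day change in hatchery CPUE, scaled.

    Divided by its SD but not centered, so "no change in hatchery fish" stays
    exactly zero. The input must be gap-free (interpolate first). An all-zero
    difference series (no hatchery fish at all) is emitted as zeros with a
    warning rather than an error.
    """
    values = _check_not_scaled(hatchery_cpue)
    if not np.all(np.isfinite(values)):
        raise ValueError("hatchery series has gaps; apply interpolate_gaps first")
    diff = lag_difference(values)
    scaled, meta = scale_covariate(diff, center=False)
    return scaled, meta


def trailing_anomaly(series, window_days: int = 32) -> np.ndarray:
    """Departure from the trailing mean of the ``window_days`` days before day i.

    The window excludes the current day: anomaly_i = v_i - mean(v_{i-w}..v_{i-1}).
    The first ``window_days`` elements have no full history and come back NaN.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    series = np.asarray(series, dtype=float)
    trailing = pd.Series(series).rolling(window_days).mean().shift(1).to_numpy()
    return series - trailing


def median_migration_day(days, counts) -> int:
    """Smallest day by which at least half of the year's catch has passed.

    Missing days contribute zero fish (they cannot move the cumulative total).
    """
    days = np.asarray(days)
    counts = np.nan_to_num(np.asarray(counts, dtype=float), nan=0.0)
    total = counts.sum()
    if total <= 0:
        raise ChainUnusableError("no fish caught; median migration day undefined")
    idx = int(np.argmax(np.cumsum(counts) >= 0.5 * total))
    return int(days[idx])


def season_covariate(days, median_day: float) -> tuple[ScaledArray, dict]:
    """Linear time covariate: (median migration day - day), scaled but not
    centered so it stays exactly zero on the median day and positive before it.
    """
    raw = float(median_day) - np.asarray(days, dtype=float)
    return scale_covariate(raw, center=False)


def scale_covariate(series, center: bool) -> tuple[ScaledArray, dict]:
    """Standardize a series per chain: z-score, or SD-division only.

    Scale-only transforms keep zeros at zero (no-change days, the median
    migration day). Zero-SD series come back as zeros with a warning.
    """
    values = _check_not_scaled(series)
    obs = np.isfinite(values)
    mean = float(np.mean(values[obs])) if center else 0.0
    ddof = 1 if obs.sum() > 1 else 0  # sample SD, as R's scale() uses
    sd = float(np.std(values[obs], ddof=ddof))
    if sd == 0.0:
        warnings.warn("zero-variance series; emitting all-zero covariate")
        out = np.where(obs, 0.0, np.nan)
        return ScaledArray(out, mean, 0.0), {"mean": mean, "sd": 0.0}
    out = (values - mean) / sd
    return ScaledArray(out, mean, sd), {"mean": mean, "sd": sd}


def interpolate_gaps(series) -> tuple[np.ndarray, dict]:
    """Fill missing values: interior gaps linearly, edges by nearest value.

    Returns the filled series and a report with the count and fraction filled.
    """
    values = np.asarray(series, dtype=float)
    obs = np.isfinite(values)
    if not obs.any():
        raise ValueError("entirely-missing series cannot be interpolated")
    n_missing = int((~obs).sum())
    idx = np.arange(len(values))
    # np.interp clamps outside the observed support = nearest-value extension
    filled = np.interp(idx, idx[obs], values[obs])
    report = {
        "n_filled": n_missing,
        "fraction_filled": n_missing / len(values),
        "filled_index": idx[~obs].tolist(),
    }
    return filled, report


def screen_collinearity(
    covariates: dict[str, np.ndarray],
    response=None,
    threshold: float = 0.5,
) -> list[dict]:
    """Flag covariate pairs too correlated to enter a model together.

    Pearson correlation over complete observations, |r| rounded half-up to one
    decimal; pairs at or above ``threshold`` are flagged. Which member of a
    flagged pair survives (the lower-AICc one) is decided by the selection
    module.
    """
    flagged = []
    for a, b in itertools.combinations(covariates, 2):
        x = np.asarray(covariates[a], dtype=float)
        y = np.asarray(covariates[b], dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise ValueError(f"pair ({a}, {b}) has fewer than 3 complete observations")
        with np.errstate(invalid="ignore"):
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        if math.isnan(r):  # a zero-variance member cannot be collinear
            continue
        if round_half_up(abs(r), 1) >= threshold:
            flagged.append({"pair": (a, b), "r": r})
    return flagged


# ---------------------------------------------------------------------------
# panel assembly
# ---------------------------------------------------------------------------


def _covariate_series(daily: pd.DataFrame, spec: CovariateSpec, median_day: float):
    """Raw (unscaled) covariate over a chain's full-season day grid."""
    days = daily["day_of_year"].to_numpy()
    if spec.transform == "season":
        return float(median_day) - days.astype(float), None
    source = daily[spec.source].to_numpy(dtype=float)
    report = None
    if not np.all(np.isfinite(source)):
        source, report = interpolate_gaps(source)
    if spec.transform == "anomaly":
        return trailing_anomaly(source, spec.window_days), report
    if spec.transform == "difference":
        return lag_difference(source), report
    return source, report


def build_panels(
    trap: pd.DataFrame,
    env: pd.DataFrame,
    first_day: int,
    last_day: int,
    covariates: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES,
    periods: tuple[str, ...] | None = None,
    unmarked_as_wild: bool = True,
) -> tuple[list[ChainPanel], dict]:
    """Assemble one ChainPanel per usable (year, period) chain.

    Transforms are computed over the full season (so anomalies and differences
    have real history at the window start) and then clipped to the analysis
    window [first_day, last_day]; all standardization uses window days only.
    The median migration day uses wild counts pooled across periods per year,
    within the window.
    """
    if first_day >= last_day:
        raise ValueError("analysis window start must precede its end")
    report: dict = {"chains": {}, "dropped": {}}
    cpue = compute_cpue(trap, unmarked_as_wild=unmarked_as_wild)
    env = env.sort_values(["year", "day_of_year"])
    if periods is None:
        periods = tuple(p for p in PERIODS if p in set(cpue["period"]))

    panels: list[ChainPanel] = []
    for year, env_year in env.groupby("year"):
        cpue_year = cpue[cpue["year"] == year]
        if cpue_year.empty:
            continue
        in_window = cpue_year["day_of_year"].between(first_day, last_day)
        try:
            median_day = median_migration_day(
                *_pooled_wild(cpue_year[in_window], first_day, last_day)
            )
        except ChainUnusableError as err:
            report["dropped"][int(year)] = f"median day: {err}"
            continue
        report["chains"][int(year)] = {"median_day": median_day}

        for period in periods:
            key = ChainKey(int(year), period)
            chain = cpue_year[cpue_year["period"] == period]
            if chain.empty:
                continue
            daily = env_year.merge(
                chain[["day_of_year", "wild_cpue", "hatchery_cpue"]],
                on="day_of_year",
                how="left",
            ).sort_values("day_of_year")
            window = daily["day_of_year"].between(first_day, last_day).to_numpy()
            try:
                panel = _assemble_chain(key, daily, window, covariates, median_day)
            except ChainUnusableError as err:
                report["dropped"][f"{year}/{period}"] = str(err)
                continue
            panels.append(panel)
    if not panels:
        raise ChainUnusableError("no usable chains in the dataset")
    return panels, report


def _pooled_wild(cpue_window: pd.DataFrame, first_day: int, last_day: int):
    pooled = cpue_window.groupby("day_of_year")["wild_count"].sum(min_count=1)
    pooled = pooled.reindex(range(first_day, last_day + 1))
    return pooled.index.to_numpy(), pooled.to_numpy()


def _assemble_chain(key, daily, window, covariates, median_day) -> ChainPanel:
    days = daily["day_of_year"].to_numpy()[window]
    response, resp_meta = log_scale_response(
        daily["wild_cpue"].to_numpy(dtype=float)[window]
    )
    cov_values: dict[str, np.ndarray] = {}
    scaling = {"response": (resp_meta["mean"], resp_meta["sd"])}
    fills: dict[str, dict] = {}
    for spec in covariates:
        raw, fill = _covariate_series(daily, spec, median_day)
        clipped = raw[window]
        if not np.all(np.isfinite(clipped)):
            n_bad = int((~np.isfinite(clipped)).sum())
            raise ChainUnusableError(
                f"covariate {spec.name!r} has {n_bad} undefined values in the "
                "analysis window (insufficient pre-window history)"
            )
        scaled, meta = scale_covariate(clipped, center=spec.center)
        cov_values[spec.name] = np.asarray(scaled)
        scaling[spec.name] = (meta["mean"], meta["sd"])
        if fill is not None:
            in_window_fill = [i for i in fill["filled_index"] if window[i]]
            fills[spec.name] = {
                "n_filled": len(in_window_fill),
                "fraction_filled": len(in_window_fill) / int(window.sum()),
            }
    panel = ChainPanel(
        key=key,
        day_of_year=days,
        response=np.asarray(response),
        covariates=cov_values,
        interpolation_report=fills,
        scaling=scaling,
    )
    panel.validate()
    return panel
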