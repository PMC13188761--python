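"""Readers, writers and run configuration.

All tabular artifacts are plain CSV; fits and reports are JSON. Dates are
handled as (year, day-of-year) integer pairs throughout — the native
coordinate of migration-timing data — with a helper to convert ISO dates on
ingest.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sensitivity import ReleaseEvent
from .transforms import CovariateSpec, DEFAULT_COVARIATES, ORIGINS, PERIODS

__all__ = [
    "RunConfig",
    "MalformedTableError",
    "read_trap_csv",
    "read_env_csv",
    "read_releases_csv",
    "write_json",
    "read_json",
    "iso_to_year_day",
    "file_sha256",
]

TRAP_COLUMNS = ("year", "day_of_year", "period", "origin", "count", "effort_hours")
ENV_COLUMNS = ("year", "day_of_year", "flow", "temperature")
RELEASE_COLUMNS = ("year", "day_of_year", "n_released", "unmarked_fraction")


class MalformedTableError(ValueError):
    """A delimited input failed validation; the message cites the file line."""


def iso_to_year_day(date: str | datetime.date) -> tuple[int, int]:
    """ISO date -> (year, day-of-year)."""
    if isinstance(date, str):
        date = datetime.date.fromisoformat(date)
    return date.year, date.timetuple().tm_yday


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedTableError(f"{path}: missing columns {missing}")


def _lines(index) -> str:
    # +2: one for the header row, one for 0- vs 1-based indexing
    return ", ".join(str(i + 2) for i in list(index[:5]))


def read_trap_csv(path: str | Path) -> pd.DataFrame:
    """Typed, validated trap-check records.

    Rejects unknown origin or period labels, negative counts, non-positive
    effort and duplicate (year, day, period, origin) keys, citing the file
    line numbers. An empty file with a header is a valid empty table.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRAP_COLUMNS, path)
    if df.empty:
        return df.astype(
            {"year": int, "day_of_year": int, "count": int, "effort_hours": float},
            errors="ignore",
        )
    bad = ~df["origin"].isin(ORIGINS)
    if bad.any():
        raise MalformedTableError(
            f"{path}: unknown origin labels {sorted(df.loc[bad, 'origin'].unique())} "
            f"at lines {_lines(df.index[bad])}"
        )
    bad = ~df["period"].isin(PERIODS)
    if bad.any():
        raise MalformedTableError(
            f"{path}: unknown period labels at lines {_lines(df.index[bad])}"
        )
    bad = df["count"] < 0
    if bad.any():
        raise MalformedTableError(
            f"{path}: negative counts at lines {_lines(df.index[bad])}"
        )
    bad = df["effort_hours"] <= 0
    if bad.any():
        raise MalformedTableError(
            f"{path}: non-positive effort at lines {_lines(df.index[bad])}"
        )
    dup = df.duplicated(subset=["year", "day_of_year", "period", "origin"], keep=False)
    if dup.any():
        raise MalformedTableError(
            f"{path}: duplicate (year, day, period, origin) keys at lines "
            f"{_lines(df.index[dup])}"
        )
    return df.astype(
        {"year": int, "day_of_year": int, "count": int, "effort_hours": float}
    )


def read_env_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ENV_COLUMNS, path)
    dup = df.duplicated(subset=["year", "day_of_year"], keep=False)
    if dup.any():
        raise MalformedTableError(
            f"{path}: duplicate (year, day) keys at lines {_lines(df.index[dup])}"
        )
    return df.astype({"year": int, "day_of_year": int})


def read_releases_csv(path: str | Path) -> list[ReleaseEvent]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, RELEASE_COLUMNS, path)
    events = []
    for i, row in df.iterrows():
        try:
            events.append(
                ReleaseEvent(
                    year=int(row["year"]),
                    day_of_year=int(row["day_of_year"]),
                    n_released=int(row["n_released"]),
                    unmarked_fraction=float(row["unmarked_fraction"]),
                )
            )
        except (ValueError, TypeError) as err:
            raise MalformedTableError(f"{path}: line {i + 2}: {err}") from err
    return events


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one end-to-end pipeline run needs.

    The shipped per-river analysis windows follow the study design this
    package reimplements (e.g. days 130-200 for Dungeness Chinook); synthetic
    runs use the generator's window.
    """

    label: str = "synthetic"
    trap_path: str | None = None
    env_path: str | None = None
    releases_path: str | None = None
    first_day: int = 41
    last_day: int = 120
    periods: tuple[str, ...] | None = None
    covariates: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES
    anomaly_window_days: int = 32
    collinearity_threshold: float = 0.5
    importance_threshold: float = 0.9
    equal_support_delta: float = 2.0
    hatchery_split_by_period: bool = False
    mislabel_rates: tuple[float, ...] = (0.0, 0.25, 0.5)
    baseline_unmarked_fraction: float = 0.05
    exclude_years: tuple[int, ...] = ()
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.first_day >= self.last_day:
            raise ValueError("analysis window start must precede its end")
        if not 0.0 < self.collinearity_threshold <= 1.0:
            raise ValueError("collinearity threshold must lie in (0, 1]")
        if not 0.0 < self.importance_threshold <= 1.0:
            raise ValueError("importance threshold must lie in (0, 1]")
        specs = []
        for cov in self.covariates:
            if isinstance(cov, dict):
                specs.append(CovariateSpec(**cov))
            else:
                specs.append(
                    dataclasses.replace(cov, window_days=self.anomaly_window_days)
                    if cov.transform == "anomaly"
                    else cov
                )
        self.covariates = tuple(specs)
        if self.periods is not None:
            self.periods = tuple(self.periods)
        self.mislabel_rates = tuple(float(r) for r in self.mislabel_rates)
        self.exclude_years = tuple(int(y) for y in self.exclude_years)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["covariates"] = [dataclasses.asdict(c) for c in self.covariates]
        return out

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
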