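"""Candidate enumeration, AICc ranking, Akaike weights and variable importance.

The selection sequence mirrors the analysis pipeline: (1) the process-variance
structure (shared vs day/night) is chosen once on the full covariate set;
(2) covariate pairs flagged by the collinearity screen are resolved by
single-covariate fits (lower AICc wins; ties within 2 AICc units keep both
members as alternative branches); (3) every subset of the retained covariates
that respects the pairwise exclusions is fitted and ranked. A variable's
relative importance is the summed Akaike weight of the candidate models that
contain it; importance >= 0.9 flags it as important.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ssm import HATCHERY, FitOptions, FitResult, ModelSpec, fit_mle
from .transforms import ChainPanel

__all__ = [
    "SelectionTable",
    "select_variance_structure",
    "resolve_correlated_pairs",
    "enumerate_candidates",
    "rank_models",
    "variable_importance",
    "fit_candidates",
]

EQUAL_SUPPORT_DELTA = 2.0
IMPORTANCE_THRESHOLD = 0.9


@dataclass
class SelectionRow:
    spec: ModelSpec
    loglik: float
    K: int
    aicc: float
    delta_aicc: float = np.nan
    weight: float = np.nan
    fit: FitResult | None = None


@dataclass
class SelectionTable:
    """Ranked candidates with weights, importance and the equal-support set."""

    rows: list[SelectionRow]
    importance: dict[str, float] = field(default_factory=dict)
    important_flags: dict[str, bool] = field(default_factory=dict)
    dropped: list[dict] = field(default_factory=list)

    @property
    def best(self) -> SelectionRow:
        return self.rows[0]

    @property
    def equal_support_set(self) -> list[SelectionRow]:
        return [row for row in self.rows if row.delta_aicc < EQUAL_SUPPORT_DELTA]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [row.spec.label() for row in self.rows],
                "variance_structure": [
                    row.spec.process_variance_structure for row in self.rows
                ],
                "hatchery_split": [
                    row.spec.hatchery_split_by_period for row in self.rows
                ],
                "loglik": [row.loglik for row in self.rows],
                "K": [row.K for row in self.rows],
                "AICc": [row.aicc for row in self.rows],
                "delta_AICc": [row.delta_aicc for row in self.rows],
                "akaike_weight": [row.weight for row in self.rows],
            }
        )


def select_variance_structure(
    panels: list[ChainPanel],
    covariates: tuple[str, ...],
    hatchery_split: bool = False,
    options: FitOptions | None = None,
) -> tuple[str, dict]:
    """Choose shared vs per-period process variance on the full covariate set.

    Single-period data is trivially 'shared'. A non-converged fit on either
    side falls back to 'shared' with a warning, since the simpler structure
    is the safer default.
    """
    periods = {p.key.period for p in panels}
    if len(periods) < 2:
        return "shared", {"reason": "single period present"}
    fits = {}
    for structure in ("shared", "by_period"):
        spec = ModelSpec(
            covariate_names=covariates,
            hatchery_split_by_period=hatchery_split and HATCHERY in covariates,
            process_variance_structure=structure,
        )
        fits[structure] = fit_mle(spec, panels, options=_fast(options))
    report = {
        s: {"aicc": f.aicc, "loglik": f.loglik, "converged": f.converged}
        for s, f in fits.items()
    }
    if not all(f.converged for f in fits.values()):
        warnings.warn("variance-structure fit did not converge; using 'shared'")
        return "shared", report
    chosen = min(fits, key=lambda s: fits[s].aicc)
    return chosen, report


def resolve_correlated_pairs(
    panels: list[ChainPanel],
    flagged_pairs: list[dict],
    all_covariates: tuple[str, ...],
    variance_structure: str = "shared",
    hatchery_split: bool = False,
    options: FitOptions | None = None,
) -> tuple[list[tuple[str, ...]], dict]:
    """Resolve each flagged pair by comparing the two single-covariate models.

    The lower-AICc member is retained; when the pair has equal support
    (|delta AICc| < 2) both members are kept as alternative covariate-set
    branches, reported explicitly. Returns the list of retained covariate
    sets (one per branch) and a per-pair report.
    """
    if not flagged_pairs:
        return [tuple(all_covariates)], {}
    report: dict = {}
    single_fit_cache: dict[str, FitResult] = {}

    def single_aicc(name: str) -> float:
        if name not in single_fit_cache:
            spec = ModelSpec(
                covariate_names=(name,),
                hatchery_split_by_period=hatchery_split and name == HATCHERY,
                process_variance_structure=variance_structure,
            )
            single_fit_cache[name] = fit_mle(spec, panels, options=_fast(options))
        return single_fit_cache[name].aicc

    branches: list[list[str]] = [list(all_covariates)]
    for entry in flagged_pairs:
        a, b = entry["pair"]
        aicc_a, aicc_b = single_aicc(a), single_aicc(b)
        winner, loser = (a, b) if aicc_a <= aicc_b else (b, a)
        tie = abs(aicc_a - aicc_b) < EQUAL_SUPPORT_DELTA
        report[(a, b)] = {
            "aicc": {a: aicc_a, b: aicc_b},
            "winner": winner,
            "equal_support": tie,
        }
        new_branches = []
        for branch in branches:
            keep_winner = [c for c in branch if c != loser]
            new_branches.append(keep_winner)
            if tie:
                keep_loser = [c for c in branch if c != winner]
                new_branches.append(keep_loser)
        # deduplicate while keeping order
        seen, branches = set(), []
        for branch in new_branches:
            key = tuple(branch)
            if key not in seen:
                seen.add(key)
                branches.append(branch)
    return [tuple(b) for b in branches], report


def enumerate_candidates(
    covariates: tuple[str, ...],
    excluded_pairs: tuple[tuple[str, str], ...] = (),
    hatchery_split: bool = False,
    variance_structure: str = "shared",
) -> list[ModelSpec]:
    """All covariate subsets (including the bare random walk) that respect
    the pairwise exclusion constraints."""
    specs = []
    for size in range(len(covariates) + 1):
        for subset in itertools.combinations(covariates, size):
            chosen = set(subset)
            if any(a in chosen and b in chosen for a, b in excluded_pairs):
                continue
            specs.append(
                ModelSpec(
                    covariate_names=subset,
                    hatchery_split_by_period=hatchery_split and HATCHERY in subset,
                    process_variance_structure=variance_structure,
                )
            )
    return specs


def fit_candidates(
    specs: list[ModelSpec],
    panels: list[ChainPanel],
    options: FitOptions | None = None,
) -> list[FitResult]:
    return [fit_mle(spec, panels, options=_fast(options)) for spec in specs]


def rank_models(fits: list[FitResult]) -> SelectionTable:
    """Rank converged fits by AICc and attach Akaike weights.

    Non-converged fits are excluded from the weight normalization and listed
    in ``dropped`` rather than silently weighted zero.
    """
    dropped = [
        {"model": f.spec.label(), "reason": "non-converged"}
        for f in fits
        if not f.converged
    ]
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValueError("no converged fits to rank")
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs.min()
    weights = np.exp(-0.5 * delta)
    weights = weights / weights.sum()
    order = np.argsort(aiccs, kind="stable")
    rows = [
        SelectionRow(
            spec=fits[i].spec,
            loglik=fits[i].loglik,
            K=fits[i].K,
            aicc=fits[i].aicc,
            delta_aicc=float(delta[i]),
            weight=float(weights[i]),
            fit=fits[i],
        )
        for i in order
    ]
    table = SelectionTable(rows=rows, dropped=dropped)
    table.importance, table.important_flags = variable_importance(table)
    return table


def variable_importance(
    table: SelectionTable, threshold: float = IMPORTANCE_THRESHOLD
) -> tuple[dict[str, float], dict[str, bool]]:
    """Summed Akaike weight of the models containing each variable.

    The hatchery covariate counts as one variable whether or not its
    coefficient is split by period.
    """
    names: list[str] = []
    for row in table.rows:
        for name in row.spec.covariate_names:
            if name not in names:
                names.append(name)
    importance = {
        name: float(
            sum(row.weight for row in table.rows if name in row.spec.covariate_names)
        )
        for name in names
    }
    flags = {name: value >= threshold for name, value in importance.items()}
    return importance, flags


def _fast(options: FitOptions | None) -> FitOptions:
    """Selection fits skip CI computation; uncertainty is computed for the
    best model afterwards."""
    options = options or FitOptions()
    if options.compute_ci:
        import dataclasses

        options = dataclasses.replace(options, compute_ci=False)
    return options
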