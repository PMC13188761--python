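"""End-to-end orchestration: transform -> variance structure -> collinearity
-> enumeration -> selection -> best-fit diagnostics -> sensitivity.

Every run writes a self-describing directory (panel, selection table, best
fit, diagnostics, sensitivity, provenance manifest) stamped with the config
hash and seed; a rerun with the same config and inputs is bit-identical.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, selection as sel, sensitivity as sens, transforms
from .ssm import FitOptions, ModelSpec, fit_mle, residual_diagnostics
from .transforms import build_panels, screen_collinearity

__all__ = ["run_pipeline", "panels_to_frame"]

log = logging.getLogger("piedpiper")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def panels_to_frame(panels) -> pd.DataFrame:
    """Tidy per-chain covariate table (one row per chain-day)."""
    frames = []
    for panel in panels:
        data = {
            "year": panel.key.year,
            "period": panel.key.period,
            "day_of_year": panel.day_of_year,
            "response": panel.response,
        }
        data.update(panel.covariates)
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def _stage(name, func, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = func(*args, **kwargs)
    except Exception as err:
        raise PipelineError(name, err) from err
    log.info("stage %-18s %6.2fs", name, time.perf_counter() - t0)
    return out


def run_pipeline(
    config: io.RunConfig,
    outdir: str | Path,
    trap: pd.DataFrame | None = None,
    env: pd.DataFrame | None = None,
    releases=None,
) -> dict:
    """Run the full analysis and write its artifacts under ``outdir``.

    Inputs come from the config's file paths unless passed in-memory.
    Returns a summary dict (best model, importance, file map).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "label": config.label,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "inputs": {},
        "stages": [],
    }
    if trap is None:
        if config.trap_path is None:
            raise PipelineError("read", ValueError("no trap data supplied"))
        trap = _stage("read_trap", io.read_trap_csv, config.trap_path)
        manifest["inputs"]["trap"] = io.file_sha256(config.trap_path)
    if env is None:
        if config.env_path is None:
            raise PipelineError("read", ValueError("no environmental data supplied"))
        env = _stage("read_env", io.read_env_csv, config.env_path)
        manifest["inputs"]["env"] = io.file_sha256(config.env_path)
    if releases is None and config.releases_path is not None:
        releases = _stage("read_releases", io.read_releases_csv, config.releases_path)

    options = FitOptions(n_starts=config.n_starts, seed=config.seed)

    # --- transform ---------------------------------------------------------
    panels, panel_report = _stage(
        "transform",
        build_panels,
        trap,
        env,
        config.first_day,
        config.last_day,
        covariates=config.covariates,
        periods=config.periods,
    )
    panels_to_frame(panels).to_csv(outdir / "panel.csv", index=False)
    io.write_json(
        {
            "chains": panel_report,
            "interpolation": {
                f"{p.key.year}/{p.key.period}": p.interpolation_report for p in panels
            },
        },
        outdir / "interpolation_report.json",
    )
    covariate_names = tuple(c.name for c in config.covariates)
    periods_present = {p.key.period for p in panels}
    split = config.hatchery_split_by_period and len(periods_present) > 1

    # --- variance structure ------------------------------------------------
    structure, structure_report = _stage(
        "variance_structure",
        sel.select_variance_structure,
        panels,
        covariate_names,
        hatchery_split=split,
        options=options,
    )

    # --- collinearity screen and pair resolution ---------------------------
    pooled = {
        name: np.concatenate([p.covariates[name] for p in panels])
        for name in covariate_names
    }
    flagged = _stage(
        "collinearity",
        screen_collinearity,
        pooled,
        threshold=config.collinearity_threshold,
    )
    branches, pair_report = _stage(
        "resolve_pairs",
        sel.resolve_correlated_pairs,
        panels,
        flagged,
        covariate_names,
        variance_structure=structure,
        hatchery_split=split,
        options=options,
    )

    # --- enumeration and selection (over all branches) ---------------------
    all_fits = []
    seen_specs = set()
    for branch in branches:
        for spec in sel.enumerate_candidates(
            branch, hatchery_split=split, variance_structure=structure
        ):
            key = (spec.covariate_names, spec.hatchery_split_by_period,
                   spec.process_variance_structure)
            if key not in seen_specs:
                seen_specs.add(key)
                all_fits.append(spec)
    fits = _stage("fit_candidates", sel.fit_candidates, all_fits, panels, options)
    table = _stage("rank", sel.rank_models, fits)
    table.to_dataframe().to_csv(outdir / "selection.csv", index=False)

    # --- best fit with uncertainty and diagnostics -------------------------
    best_spec = table.best.spec
    best_fit = _stage("best_fit", fit_mle, best_spec, panels, options=options)
    io.write_json(best_fit.to_dict(), outdir / "best_fit.json")
    diagnostics = _stage("diagnostics", residual_diagnostics, best_fit)
    diagnostics.to_frame().to_csv(outdir / "diagnostics.csv", index=False)

    # --- sensitivity -------------------------------------------------------
    sensitivity_summary = {}
    if releases:
        corr = _stage(
            "unmarked_correlation", sens.unmarked_release_correlation, trap, releases
        )
        sensitivity_summary["unmarked_release_correlation"] = {
            "r": corr.r,
            "n_pairs": len(corr.pairs),
            "dropped": corr.dropped,
            "leave_one_out": corr.leave_one_out.to_dict("records"),
        }
    if sens_has_hatchery(best_spec) and config.mislabel_rates:
        mis = _stage(
            "mislabeling",
            sens.mislabeling_sensitivity,
            trap,
            env,
            best_spec,
            config.mislabel_rates,
            config.first_day,
            config.last_day,
            covariates=config.covariates,
            baseline_fraction=config.baseline_unmarked_fraction,
            seed=config.seed,
            options=options,
        )
        sensitivity_summary["mislabeling"] = mis.to_dict()
    for year in config.exclude_years:
        result = _stage(
            "exclude_year", sens.exclude_year_refit, panels, best_spec, year, options
        )
        sensitivity_summary[f"exclude_year_{year}"] = {
            "coefficient_deltas": result["coefficient_deltas"],
            "full_se": result["full_se"],
        }
    if sensitivity_summary:
        io.write_json(sensitivity_summary, outdir / "sensitivity.json")

    summary = {
        "best_model": best_spec.label(),
        "variance_structure": structure,
        "variance_structure_report": structure_report,
        "collinearity_flags": [
            {"pair": list(f["pair"]), "r": f["r"]} for f in flagged
        ],
        "pair_resolution": {f"{a}|{b}": v for (a, b), v in pair_report.items()},
        "branches": [list(b) for b in branches],
        "importance": table.importance,
        "important_flags": table.important_flags,
        "best_fit": best_fit.to_dict(),
        "n_candidates": len(all_fits),
        "dropped_candidates": table.dropped,
    }
    manifest["summary"] = {
        "best_model": summary["best_model"],
        "variance_structure": structure,
        "n_candidates": len(all_fits),
    }
    io.write_json(manifest, outdir / "manifest.json")
    io.write_json(summary, outdir / "summary.json")
    return summary


def sens_has_hatchery(spec: ModelSpec) -> bool:
    from .ssm import HATCHERY

    return HATCHERY in spec.covariate_names
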