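"""Multivariate autoregressive state-space model over (year, period) chains.

The observed standardized log-CPUE of wild smolts in each chain follows a
log-scale random walk driven by covariate effects:

    observation:  y_t = x_t + v_t,              v_t ~ N(0, r)
    process:      x_t = x_{t-1} + B c_t + w_t,  w_t ~ N(0, q)

Chains are independent but share parameters: environmental coefficients are
tied across all chains, the hatchery coefficient may be split day/night, the
process variance may be shared or per-period, and the observation variance is
one scalar. Estimation is direct maximum likelihood through the missing-aware
Kalman filter (variances optimized on the log scale), with moment-based
initialization plus jittered restarts; standard errors come from the inverse
numerical Hessian of the negative log-likelihood at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import kalman
from .transforms import ChainKey, ChainPanel

__all__ = [
    "ModelSpec",
    "SSMParams",
    "FitOptions",
    "FitResult",
    "ModelDesign",
    "build_model",
    "kalman_loglik",
    "fit_mle",
    "smooth_states",
    "aicc",
    "residual_diagnostics",
    "confidence_intervals",
    "simulate_from_model",
]

HATCHERY = "hatchery_diff"


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: covariate subset and variance/coefficient structure."""

    covariate_names: tuple[str, ...]
    hatchery_split_by_period: bool = False
    process_variance_structure: str = "shared"  # or "by_period"

    def __post_init__(self):
        if self.process_variance_structure not in ("shared", "by_period"):
            raise ValueError("variance structure must be 'shared' or 'by_period'")
        if self.hatchery_split_by_period and HATCHERY not in self.covariate_names:
            raise ValueError("hatchery split requires the hatchery covariate")

    def coefficient_slots(self) -> tuple[str, ...]:
        slots = []
        for name in self.covariate_names:
            if name == HATCHERY and self.hatchery_split_by_period:
                slots.extend([f"{HATCHERY}_day", f"{HATCHERY}_night"])
            else:
                slots.append(name)
        return tuple(slots)

    def label(self) -> str:
        return "+".join(self.covariate_names) if self.covariate_names else "(none)"


@dataclass
class SSMParams:
    """Fitted or supplied parameters on the natural scale."""

    B: dict[str, float]
    q: dict[str, float]  # {'shared': q} or {'day': q_d, 'night': q_n}
    r: float
    x0: dict[ChainKey, float] | None = None
    V0: float = 5.0

    def q_for(self, period: str) -> float:
        return self.q["shared"] if "shared" in self.q else self.q[period]


@dataclass
class FitOptions:
    """Optimizer settings; deterministic given ``seed``."""

    n_starts: int = 5
    seed: int = 0
    jitter: float = 0.3
    maxiter: int = 500
    agree_tol: float = 1e-6  # relative loglik agreement between best two starts
    v0: float = 5.0
    estimate_x0: bool = False  # alternative convention: x0 free, counted in K
    fix_r: float | None = None  # hold the observation variance at a known value
    compute_ci: bool = True
    engine: str = "auto"


@dataclass
class ModelDesign:
    """Chains stacked into dense arrays with the parameter index maps."""

    spec: ModelSpec
    chains: list[ChainKey]
    Y: np.ndarray  # (nc, T) response, NaN = missing (incl. padding)
    X: np.ndarray  # (nc, T, n_slots) covariates mapped to coefficient slots
    slot_names: tuple[str, ...]
    q_slots: tuple[str, ...]
    q_index: np.ndarray  # (nc,) chain -> q slot
    m0: np.ndarray  # (nc,) initial state means (first observed response)
    lengths: np.ndarray  # (nc,) true chain lengths before padding

    @property
    def n_eff(self) -> int:
        return int(np.isfinite(self.Y).sum())

    @property
    def n_coef(self) -> int:
        return len(self.slot_names)

    def drift(self, beta: np.ndarray) -> np.ndarray:
        return self.X @ beta

    def K(self, estimate_x0: bool = False) -> int:
        k = self.n_coef + len(self.q_slots) + 1
        return k + len(self.chains) if estimate_x0 else k


def build_model(spec: ModelSpec, panels: list[ChainPanel]) -> ModelDesign:
    """Realize parameter sharing as per-chain design matrices.

    Each chain's covariate columns are mapped onto global coefficient slots;
    when the hatchery coefficient is split, a chain's hatchery column feeds
    the slot of its own period and zero elsewhere. Chains of unequal length
    are padded with missing observations and zero drift, which leaves the
    likelihood untouched.
    """
    if not panels:
        raise ValueError("no panels supplied")
    for panel in panels:
        for name in spec.covariate_names:
            if name not in panel.covariates:
                raise ValueError(
                    f"covariate {name!r} missing from chain {panel.key}"
                )
    periods = {p.key.period for p in panels}
    if spec.process_variance_structure == "by_period" and len(periods) < 2:
        raise ValueError("by_period variance structure needs both periods present")
    if spec.hatchery_split_by_period and len(periods) < 2:
        raise ValueError("hatchery day/night split needs both periods present")

    slot_names = spec.coefficient_slots()
    q_slots = (
        ("shared",)
        if spec.process_variance_structure == "shared"
        else ("day", "night")
    )
    nc = len(panels)
    T = max(len(p.day_of_year) for p in panels)
    Y = np.full((nc, T), np.nan)
    X = np.zeros((nc, T, len(slot_names)))
    q_index = np.zeros(nc, dtype=np.intp)
    m0 = np.zeros(nc)
    lengths = np.zeros(nc, dtype=np.intp)
    for i, panel in enumerate(panels):
        n = len(panel.day_of_year)
        lengths[i] = n
        Y[i, :n] = panel.response
        for j, slot in enumerate(slot_names):
            if slot.startswith(f"{HATCHERY}_"):
                if slot.removeprefix(f"{HATCHERY}_") == panel.key.period:
                    X[i, :n, j] = panel.covariates[HATCHERY]
            else:
                X[i, :n, j] = panel.covariates[slot]
        if len(q_slots) == 2:
            q_index[i] = q_slots.index(panel.key.period)
        finite = np.isfinite(panel.response)
        m0[i] = panel.response[finite][0] if finite.any() else 0.0
    return ModelDesign(
        spec=spec,
        chains=[p.key for p in panels],
        Y=Y,
        X=X,
        slot_names=slot_names,
        q_slots=q_slots,
        q_index=q_index,
        m0=m0,
        lengths=lengths,
    )


def _params_to_vectors(design: ModelDesign, params: SSMParams):
    beta = np.array([params.B[s] for s in design.slot_names], dtype=float)
    qv = np.array([params.q[s] for s in design.q_slots], dtype=float)[design.q_index]
    if params.x0 is not None:
        m0 = np.array([params.x0[key] for key in design.chains], dtype=float)
    else:
        m0 = design.m0
    return beta, qv, m0


def kalman_loglik(
    params: SSMParams,
    panels: list[ChainPanel],
    spec: ModelSpec | None = None,
    engine: str = "auto",
) -> float:
    """Exact marginal log-likelihood of the data under ``params``."""
    if spec is None:
        spec = ModelSpec(covariate_names=tuple(params.B))
    design = build_model(spec, panels)
    beta, qv, m0 = _params_to_vectors(design, params)
    u = design.drift(beta)
    return kalman.loglik(design.Y, u, qv, params.r, m0, params.V0, engine=engine)


def aicc(loglik: float, K: int, n_eff: int) -> float:
    """AIC with the small-sample correction: -2 logL + 2K + 2K(K+1)/(n-K-1)."""
    if n_eff <= K + 1:
        raise ValueError(f"AICc undefined: n_eff={n_eff} <= K+1={K + 1}")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n_eff - K - 1)


# ---------------------------------------------------------------------------
# maximum likelihood
# ---------------------------------------------------------------------------

_LOGVAR_FLOOR = np.log(1e-8)


def _moment_init(design: ModelDesign) -> np.ndarray:
    """Method-of-moments start: OLS of the response increments on the
    covariates, with (q, r) from the variance and lag-1 autocovariance of the
    residual increments (for increments e_t, cov(e_t, e_{t+1}) = -r)."""
    Y, X = design.Y, design.X
    dy = Y[:, 1:] - Y[:, :-1]
    ok = np.isfinite(dy)
    rows_x = X[:, 1:, :][ok]
    rows_y = dy[ok]
    if rows_y.size < design.n_coef + 2:
        beta = np.zeros(design.n_coef)
        resid = rows_y
    else:
        beta, *_ = np.linalg.lstsq(rows_x, rows_y, rcond=None)
        resid = rows_y - rows_x @ beta
    var_e = float(np.var(resid)) if resid.size else 1.0
    var_e = max(var_e, 1e-4)
    # lag-1 autocovariance of increments within chains
    acov = 0.0
    n_pairs = 0
    e = np.full_like(dy, np.nan)
    e[ok] = resid
    pair = np.isfinite(e[:, 1:]) & np.isfinite(e[:, :-1])
    if pair.any():
        a = e[:, 1:][pair]
        b = e[:, :-1][pair]
        acov = float(np.mean(a * b))
        n_pairs = a.size
    r0 = max(-acov, 0.05 * var_e) if n_pairs else 0.25 * var_e
    r0 = min(r0, 0.9 * var_e / 2.0)
    q0 = max(var_e - 2.0 * r0, 0.05 * var_e)
    theta = np.concatenate(
        [beta, np.log(np.full(len(design.q_slots), q0)), [np.log(r0)]]
    )
    return theta


def _unpack(theta: np.ndarray, design: ModelDesign, options: "FitOptions"):
    nb, nq = design.n_coef, len(design.q_slots)
    beta = theta[:nb]
    log_q = np.clip(theta[nb : nb + nq], _LOGVAR_FLOOR, 20.0)
    if options.fix_r is None:
        r = float(np.exp(np.clip(theta[nb + nq], _LOGVAR_FLOOR, 20.0)))
        free = nb + nq + 1
    else:
        r = float(options.fix_r)
        free = nb + nq
    m0 = theta[free:] if options.estimate_x0 else design.m0
    return beta, np.exp(log_q), r, m0


def fit_mle(
    spec: ModelSpec,
    panels: list[ChainPanel],
    init: SSMParams | None = None,
    options: FitOptions | None = None,
) -> "FitResult":
    """Maximize the Kalman likelihood over (B, q, r) [and optionally x0].

    Multi-start quasi-Newton: the first start is the moment-based initializer
    (or ``init``), later starts are jittered. Starts stop early once the best
    two optima agree to ``agree_tol`` (relative), which also defines the
    ``converged`` flag. Deterministic given ``options.seed``.
    """
    options = options or FitOptions()
    design = build_model(spec, panels)
    n_eff = design.n_eff
    K = design.K(options.estimate_x0) - (1 if options.fix_r is not None else 0)
    if n_eff <= K + 1:
        raise ValueError(f"not identifiable: n_eff={n_eff} <= K+1={K + 1}")

    if init is not None:
        beta0 = np.array([init.B[s] for s in design.slot_names], dtype=float)
        theta0 = np.concatenate(
            [beta0, np.log(np.maximum([init.q[s] for s in design.q_slots], 1e-8)),
             [np.log(max(init.r, 1e-8))]]
        )
    else:
        theta0 = _moment_init(design)
    if options.fix_r is not None:
        theta0 = theta0[:-1]
    if options.estimate_x0:
        theta0 = np.concatenate([theta0, design.m0])

    Y, X, q_index = design.Y, design.X, design.q_index
    v0 = options.v0
    engine = options.engine

    def negll(theta):
        beta, qs, r, m0 = _unpack(theta, design, options)
        u = X @ beta
        ll = kalman.loglik(Y, u, qs[q_index], r, m0, v0, engine=engine)
        return -ll if np.isfinite(ll) else 1e12

    rng = np.random.default_rng(options.seed)
    optima: list[tuple[float, np.ndarray, bool]] = []
    converged = False
    for start in range(max(options.n_starts, 1)):
        if start == 0:
            theta_s = theta0
        else:
            theta_s = theta0 + rng.normal(
                0.0, options.jitter * (np.abs(theta0) + 0.1)
            )
        res = optimize.minimize(
            negll,
            theta_s,
            method="L-BFGS-B",
            options={"maxiter": options.maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        optima.append((float(res.fun), res.x, bool(res.success)))
        if len(optima) >= 2:
            best = sorted(f for f, _, _ in optima)
            scale = max(1.0, abs(best[0]))
            if (best[1] - best[0]) / scale < options.agree_tol:
                converged = True
                break
    best_fun, best_theta, best_ok = min(optima, key=lambda t: t[0])
    if options.n_starts == 1:
        converged = best_ok

    beta, qs, r, m0 = _unpack(best_theta, design, options)
    loglik = -best_fun
    params = SSMParams(
        B={s: float(b) for s, b in zip(design.slot_names, beta)},
        q={s: float(v) for s, v in zip(design.q_slots, qs)},
        r=float(r),
        x0=(
            {key: float(v) for key, v in zip(design.chains, m0)}
            if options.estimate_x0
            else None
        ),
        V0=v0,
    )
    result = FitResult(
        spec=spec,
        params=params,
        loglik=float(loglik),
        K=K,
        n_eff=n_eff,
        aicc=aicc(loglik, K, n_eff),
        converged=converged and best_ok,
        design=design,
        options=options,
        theta=best_theta,
        n_starts_used=len(optima),
    )
    if options.compute_ci:
        result.compute_uncertainty(negll)
    return result


@dataclass
class FitResult:
    """Estimates, fit statistics and uncertainty for one candidate model."""

    spec: ModelSpec
    params: SSMParams
    loglik: float
    K: int
    n_eff: int
    aicc: float
    converged: bool
    design: ModelDesign
    options: FitOptions
    theta: np.ndarray
    n_starts_used: int = 1
    se: dict[str, float] = field(default_factory=dict)
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    se_available: bool = False

    def compute_uncertainty(self, negll=None) -> None:
        """Hessian-based SEs and Wald 95% CIs for every free parameter.

        Variance SEs are delta-method transforms of the log-scale Hessian. A
        singular Hessian leaves SEs unavailable and the fit flagged.
        """
        if negll is None:
            design, options = self.design, self.options

            def negll(theta):
                beta, qs, r, m0 = _unpack(theta, design, options)
                u = design.X @ beta
                ll = kalman.loglik(
                    design.Y, u, qs[design.q_index], r, m0, options.v0,
                    engine=options.engine,
                )
                return -ll if np.isfinite(ll) else 1e12

        H = _numeric_hessian(negll, self.theta)
        has_r = self.options.fix_r is None
        names = list(self.design.slot_names) + [
            f"q_{s}" for s in self.design.q_slots
        ] + (["r"] if has_r else [])
        nb, nq = self.design.n_coef, len(self.design.q_slots)
        n_free = nb + nq + (1 if has_r else 0)
        try:
            cov = np.linalg.inv(H[:n_free, :n_free])
            diag = np.diag(cov)
            if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
                raise np.linalg.LinAlgError("non-positive Hessian diagonal")
        except np.linalg.LinAlgError:
            warnings.warn("singular observed information; SEs unavailable")
            self.se_available = False
            self.se = {}
            self.ci95 = {}
            return
        se_theta = np.sqrt(diag)
        values = list(self.theta[:nb]) + [
            self.params.q[s] for s in self.design.q_slots
        ] + ([self.params.r] if has_r else [])
        for k, (name, value) in enumerate(zip(names, values)):
            se = se_theta[k] if k < nb else se_theta[k] * value  # delta method
            self.se[name] = float(se)
            self.ci95[name] = (float(value - 1.96 * se), float(value + 1.96 * se))
        self.se_available = True

    def significant(self, name: str) -> bool:
        """A coefficient is significant when its 95% CI excludes zero."""
        lo, hi = self.ci95[name]
        return lo > 0.0 or hi < 0.0

    def hatchery_effect(self, period: str = "night") -> float | None:
        if HATCHERY in self.params.B:
            return self.params.B[HATCHERY]
        return self.params.B.get(f"{HATCHERY}_{period}")

    def to_dict(self) -> dict:
        return {
            "covariates": list(self.spec.covariate_names),
            "hatchery_split_by_period": self.spec.hatchery_split_by_period,
            "process_variance_structure": self.spec.process_variance_structure,
            "B": self.params.B,
            "q": self.params.q,
            "r": self.params.r,
            "loglik": self.loglik,
            "K": self.K,
            "n_eff": self.n_eff,
            "aicc": self.aicc,
            "converged": self.converged,
            "se": self.se,
            "ci95": {k: list(v) for k, v in self.ci95.items()},
        }


def _numeric_hessian(f, theta, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = len(theta)
    h = rel_step * (np.abs(theta) + 1.0)
    H = np.empty((n, n))
    f0 = f(theta)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej)
                    - f(theta + ei - ej)
                    - f(theta - ei + ej)
                    + f(theta - ei - ej)
                ) / (4.0 * h[i] * h[j])
    return H


def confidence_intervals(fit: FitResult) -> dict[str, tuple[float, float]]:
    """Per-parameter 95% Wald intervals (computing them if not yet done)."""
    if not fit.se_available and not fit.ci95:
        fit.compute_uncertainty()
    return fit.ci95


# ---------------------------------------------------------------------------
# smoothing, diagnostics, simulation
# ---------------------------------------------------------------------------


def smooth_states(
    params: SSMParams, panels: list[ChainPanel], spec: ModelSpec | None = None
) -> dict[ChainKey, dict[str, np.ndarray]]:
    """Fixed-interval smoothed state means and variances per chain."""
    if spec is None:
        spec = ModelSpec(covariate_names=tuple(params.B))
    design = build_model(spec, panels)
    beta, qv, m0 = _params_to_vectors(design, params)
    m_s, v_s, _ = kalman.smooth(design.Y, design.drift(beta), qv, params.r, m0, params.V0)
    out = {}
    for i, key in enumerate(design.chains):
        n = design.lengths[i]
        out[key] = {
            "day_of_year": panels[i].day_of_year,
            "mean": m_s[i, :n],
            "var": v_s[i, :n],
        }
    return out


@dataclass
class DiagnosticsReport:
    """Standardized one-step-ahead residual diagnostics for a fitted model."""

    innovations: dict[ChainKey, np.ndarray]
    fitted: dict[ChainKey, np.ndarray]
    acf: np.ndarray  # pooled per-lag ACF, lags 1..n_lags
    acf_band: float  # +/- 95% white-noise band
    ljung_box: dict  # per-chain and combined statistic/p-value
    qq: tuple[np.ndarray, np.ndarray]  # theoretical, sample quantiles

    def to_frame(self):
        import pandas as pd

        rows = []
        for key, e in self.innovations.items():
            for fit_val, resid in zip(self.fitted[key], e):
                rows.append(
                    {
                        "year": key.year,
                        "period": key.period,
                        "fitted": fit_val,
                        "residual": resid,
                    }
                )
        return pd.DataFrame(rows)


def residual_diagnostics(fit: FitResult, n_lags: int = 20) -> DiagnosticsReport:
    """ACF, Ljung-Box, QQ and fitted-vs-residual material from the filter
    innovations (prediction errors at observed steps, standardized by their
    one-step variances)."""
    from statsmodels.stats.diagnostic import acorr_ljungbox

    design = fit.design
    beta, qv, m0 = _params_to_vectors(design, fit.params)
    fp = kalman.filter_pass(
        design.Y, design.drift(beta), qv, fit.params.r, m0, fit.params.V0
    )
    std = fp["innov"] / np.sqrt(fp["s_innov"])
    innovations: dict[ChainKey, np.ndarray] = {}
    fitted: dict[ChainKey, np.ndarray] = {}
    per_chain_lb = {}
    q_total, df_total = 0.0, 0
    acfs = []
    for i, key in enumerate(design.chains):
        n = design.lengths[i]
        e = std[i, :n]
        ok = np.isfinite(e)
        innovations[key] = e[ok]
        fitted[key] = fp["m_pred"][i, :n][ok]
        series = e[ok]
        if series.size > n_lags + 1:
            lags = min(n_lags, series.size // 4)
            lb = acorr_ljungbox(series, lags=[lags], return_df=True)
            stat = float(lb["lb_stat"].iloc[0])
            per_chain_lb[key] = {
                "stat": stat,
                "pvalue": float(lb["lb_pvalue"].iloc[0]),
                "df": lags,
            }
            q_total += stat
            df_total += lags
            acfs.append(_acf_1d(series, n_lags))
    pooled = np.concatenate(list(innovations.values())) if innovations else np.array([])
    acf = np.nanmean(np.vstack(acfs), axis=0) if acfs else np.full(n_lags, np.nan)
    n_per_chain = np.mean([len(e) for e in innovations.values()]) if innovations else 1
    combined_p = float(stats.chi2.sf(q_total, df_total)) if df_total else np.nan
    osm = stats.norm.ppf((np.arange(1, pooled.size + 1) - 0.5) / pooled.size)
    return DiagnosticsReport(
        innovations=innovations,
        fitted=fitted,
        acf=acf,
        acf_band=1.96 / np.sqrt(max(n_per_chain, 1)),
        ljung_box={
            "per_chain": per_chain_lb,
            "combined_stat": q_total,
            "combined_df": df_total,
            "combined_pvalue": combined_p,
        },
        qq=(osm, np.sort(pooled)),
    )


def _acf_1d(x: np.ndarray, n_lags: int) -> np.ndarray:
    x = x - x.mean()
    denom = float(np.dot(x, x))
    out = np.full(n_lags, np.nan)
    if denom == 0.0:  # degenerate (all-equal) residuals
        return out
    for k in range(1, min(n_lags, len(x) - 1) + 1):
        out[k - 1] = float(np.dot(x[k:], x[:-k])) / denom
    return out


def plot_diagnostics(report: DiagnosticsReport, path=None):
    """Four-panel residual diagnostics figure (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    pooled = np.concatenate(list(report.innovations.values()))
    fitted = np.concatenate(list(report.fitted.values()))
    axes[0, 0].scatter(fitted, pooled, s=6, alpha=0.5)
    axes[0, 0].axhline(0, color="k", lw=0.5)
    axes[0, 0].set(xlabel="fitted (one-step prediction)", ylabel="std. residual")
    lags = np.arange(1, len(report.acf) + 1)
    axes[0, 1].stem(lags, report.acf)
    axes[0, 1].axhline(report.acf_band, ls="--", color="gray")
    axes[0, 1].axhline(-report.acf_band, ls="--", color="gray")
    axes[0, 1].set(xlabel="lag", ylabel="residual ACF")
    osm, osr = report.qq
    axes[1, 0].scatter(osm, osr, s=6)
    lim = [min(osm.min(), osr.min()), max(osm.max(), osr.max())]
    axes[1, 0].plot(lim, lim, color="k", lw=0.5)
    axes[1, 0].set(xlabel="normal quantiles", ylabel="residual quantiles")
    axes[1, 1].hist(pooled, bins=30, density=True)
    grid = np.linspace(-4, 4, 200)
    axes[1, 1].plot(grid, stats.norm.pdf(grid), color="k")
    axes[1, 1].set(xlabel="std. residual", ylabel="density")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def simulate_from_model(
    spec: ModelSpec,
    panels: list[ChainPanel],
    params: SSMParams,
    rng: np.random.Generator,
    x0: float = 0.0,
) -> tuple[list[ChainPanel], dict[ChainKey, np.ndarray]]:
    """Forward-simulate responses from the model over the panels' covariates.

    Returns copies of the panels with the response replaced by a simulated
    draw (original missingness pattern preserved) plus the latent states.
    Used by the parameter-recovery and selection-calibration experiments.
    """
    design = build_model(spec, panels)
    beta = np.array([params.B[s] for s in design.slot_names], dtype=float)
    u = design.drift(beta)
    out_panels = []
    latent: dict[ChainKey, np.ndarray] = {}
    for i, panel in enumerate(panels):
        n = design.lengths[i]
        q = params.q_for(panel.key.period)
        w = rng.normal(0.0, np.sqrt(q), size=n)
        x = x0 + np.cumsum(u[i, :n] + w)
        y = x + rng.normal(0.0, np.sqrt(params.r), size=n)
        y[~np.isfinite(panel.response)] = np.nan
        latent[panel.key] = x
        out_panels.append(
            ChainPanel(
                key=panel.key,
                day_of_year=panel.day_of_year.copy(),
                response=y,
                covariates={k: v.copy() for k, v in panel.covariates.items()},
                interpolation_report=dict(panel.interpolation_report),
                scaling=dict(panel.scaling),
            )
        )
    return out_panels, latent
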