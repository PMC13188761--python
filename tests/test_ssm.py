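"""State-space model construction, likelihood, ML fitting and diagnostics."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from piedpiper import kalman, ssm
from piedpiper.ssm import FitOptions, ModelSpec, SSMParams
from piedpiper.transforms import ChainKey, ChainPanel


def make_panel(year, period, T, rng, covariates=("a", "b"), missing=0.0):
    response = rng.normal(size=T)
    if missing:
        response[rng.random(T) < missing] = np.nan
    return ChainPanel(
        key=ChainKey(year, period),
        day_of_year=np.arange(41, 41 + T),
        response=response,
        covariates={name: rng.normal(size=T) for name in covariates},
    )


class TestBuildModel:
    def two_by_two_panels(self, covs):
        rng = np.random.default_rng(0)
        return [
            make_panel(y, p, 30, rng, covariates=covs)
            for y in (1, 2)
            for p in ("day", "night")
        ]

    def test_split_hatchery_adds_one_coefficient_slot(self):
        covs = ("temp_diff", "flow_diff", "season", "hatchery_diff")
        panels = self.two_by_two_panels(covs)
        split = ssm.build_model(
            ModelSpec(covariate_names=covs, hatchery_split_by_period=True), panels
        )
        assert len(split.slot_names) == 5
        pooled = ssm.build_model(ModelSpec(covariate_names=covs), panels)
        assert len(pooled.slot_names) == 4

    def test_variance_structure_slot_count(self):
        covs = ("a", "b")
        panels = self.two_by_two_panels(covs)
        shared = ssm.build_model(ModelSpec(covs), panels)
        assert shared.q_slots == ("shared",)
        by_period = ssm.build_model(
            ModelSpec(covs, process_variance_structure="by_period"), panels
        )
        assert by_period.q_slots == ("day", "night")

    def test_split_hatchery_column_feeds_own_period_slot_only(self):
        covs = ("hatchery_diff",)
        panels = self.two_by_two_panels(covs)
        design = ssm.build_model(
            ModelSpec(covs, hatchery_split_by_period=True), panels
        )
        day_col = design.slot_names.index("hatchery_diff_day")
        night_col = design.slot_names.index("hatchery_diff_night")
        for i, key in enumerate(design.chains):
            active = day_col if key.period == "day" else night_col
            inactive = night_col if key.period == "day" else day_col
            assert np.any(design.X[i, :, active] != 0)
            assert np.all(design.X[i, :, inactive] == 0)

    def test_missing_covariate_names_chain(self):
        rng = np.random.default_rng(1)
        panels = [make_panel(1, "night", 20, rng, covariates=("a",))]
        with pytest.raises(ValueError, match="'b' missing from chain"):
            ssm.build_model(ModelSpec(covariate_names=("a", "b")), panels)


class TestAICc:
    def test_hand_arithmetic(self):
        expected = 200 + 8 + 2 * 4 * 5 / 95
        assert ssm.aicc(-100.0, 4, 100) == pytest.approx(expected, abs=1e-9)

    def test_limits(self):
        assert ssm.aicc(-100.0, 4, 10**9) == pytest.approx(208.0, abs=1e-6)
        assert ssm.aicc(-50.0, 0, 100) == pytest.approx(100.0)

    def test_undefined_below_minimum_sample(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            ssm.aicc(-10.0, 5, 6)


class TestKalmanLoglik:
    def test_two_identical_chains_double_one(self, model_panels):
        panels, truth = model_panels
        spec = ModelSpec(covariate_names=("hatchery_diff", "flow_diff", "season"))
        params = SSMParams(
            B={k: v for k, v in truth["true_B"].items()},
            q={"shared": 0.05},
            r=0.1,
        )
        one = ssm.kalman_loglik(params, panels[:1], spec)
        both = ssm.kalman_loglik(params, [panels[0], panels[0]], spec)
        assert both == pytest.approx(2 * one, abs=1e-9)

    def test_splitting_into_chains_leaves_likelihood_unchanged(self, model_panels):
        panels, _ = model_panels
        spec = ModelSpec(covariate_names=("hatchery_diff", "flow_diff", "season"))
        params = SSMParams(B={n: 0.1 for n in spec.covariate_names},
                           q={"shared": 0.05}, r=0.1)
        subset = panels[:3]
        total = ssm.kalman_loglik(params, subset, spec)
        parts = sum(ssm.kalman_loglik(params, [p], spec) for p in subset)
        assert total == pytest.approx(parts, abs=1e-8)


class TestFitMLE:
    def test_local_level_matches_grid_search_oracle(self):
        # no covariates, r held at truth: 1-D likelihood in q
        rng = np.random.default_rng(21)
        T, q_true, r_true = 300, 0.2, 0.1
        x = np.cumsum(rng.normal(0, np.sqrt(q_true), T))
        y = x + rng.normal(0, np.sqrt(r_true), T)
        panel = ChainPanel(
            key=ChainKey(1, "night"),
            day_of_year=np.arange(T),
            response=y,
            covariates={},
        )
        options = FitOptions(fix_r=r_true, compute_ci=False, seed=1)
        fit = ssm.fit_mle(ModelSpec(covariate_names=()), panel and [panel],
                          options=options)
        design = ssm.build_model(ModelSpec(covariate_names=()), [panel])

        def ll(q):
            return kalman.loglik(
                design.Y, np.zeros_like(design.Y), np.array([q]), r_true,
                design.m0, options.v0,
            )

        grid = np.linspace(0.01, 1.0, 400)
        coarse = grid[np.argmax([ll(q) for q in grid])]
        fine = np.arange(coarse - 0.01, coarse + 0.01, 1e-4)
        q_grid = fine[np.argmax([ll(q) for q in fine])]
        assert fit.params.q["shared"] == pytest.approx(q_grid, abs=1e-3)
        assert fit.K == 1  # only q is free
        assert fit.converged

    def test_null_coefficients_lie_within_two_se_of_zero(self):
        # nominal ~95% per coefficient; allow Monte-Carlo slack
        rng = np.random.default_rng(22)
        hits = {"a": 0, "b": 0}
        n_rep = 100
        spec = ModelSpec(covariate_names=("a", "b"))
        params = SSMParams(B={"a": 0.0, "b": 0.0}, q={"shared": 0.05}, r=0.1)
        for rep in range(n_rep):
            base = [make_panel(y, "night", 60, rng) for y in range(4)]
            panels, _ = ssm.simulate_from_model(spec, base, params, rng)
            fit = ssm.fit_mle(spec, panels, options=FitOptions(seed=rep))
            for name in hits:
                if abs(fit.params.B[name]) <= 2 * fit.se[name]:
                    hits[name] += 1
        assert hits["a"] >= 93 and hits["b"] >= 93

    def test_zero_process_variance_truth_pushes_q_to_boundary(self):
        rng = np.random.default_rng(23)
        spec = ModelSpec(covariate_names=())
        truth = SSMParams(B={}, q={"shared": 0.0}, r=0.2)
        base = [make_panel(y, "night", 80, rng, covariates=()) for y in range(3)]
        panels, _ = ssm.simulate_from_model(spec, base, truth, rng)
        fit = ssm.fit_mle(spec, panels, options=FitOptions(compute_ci=False))
        assert fit.params.q["shared"] < 0.02
        assert fit.loglik >= ssm.kalman_loglik(truth, panels, spec) - 1e-6

    def test_deterministic_given_seed(self, model_panels, fast_options):
        panels, _ = model_panels
        spec = ModelSpec(covariate_names=("hatchery_diff", "season"))
        a = ssm.fit_mle(spec, panels, options=fast_options)
        b = ssm.fit_mle(spec, panels, options=fast_options)
        assert a.loglik == b.loglik
        assert a.params.B == b.params.B

    def test_all_zero_covariate_estimate_near_zero_and_ses_flagged(self, model_panels):
        panels, _ = model_panels
        degenerate = []
        for p in panels:
            covs = dict(p.covariates)
            covs["dead"] = np.zeros_like(p.response)
            degenerate.append(dataclasses.replace(p, covariates=covs))
        spec = ModelSpec(covariate_names=("season", "dead"))
        with pytest.warns(UserWarning, match="singular"):
            fit = ssm.fit_mle(spec, degenerate)
        assert abs(fit.params.B["dead"]) < 1e-6
        assert not fit.se_available

    def test_information_grows_with_sample_size(self):
        rng = np.random.default_rng(24)
        spec = ModelSpec(covariate_names=("a",))
        params = SSMParams(B={"a": 0.2}, q={"shared": 0.05}, r=0.1)
        ses = []
        for n_chain in (2, 6, 18):
            base = [
                make_panel(y, "night", 70, rng, covariates=("a",))
                for y in range(n_chain)
            ]
            panels, _ = ssm.simulate_from_model(spec, base, params, rng)
            fit = ssm.fit_mle(spec, panels, options=FitOptions(seed=3))
            ses.append(fit.se["a"])
        assert ses[0] > ses[1] > ses[2]


class TestSmoothStates:
    def test_near_zero_observation_noise_recovers_observations(self, model_panels):
        panels, truth = model_panels
        spec = ModelSpec(covariate_names=("hatchery_diff", "flow_diff", "season"))
        params = SSMParams(B=dict(truth["true_B"]), q={"shared": 0.05}, r=1e-12)
        smoothed = ssm.smooth_states(params, panels, spec)
        for panel in panels:
            obs = np.isfinite(panel.response)
            np.testing.assert_allclose(
                smoothed[panel.key]["mean"][obs], panel.response[obs], atol=1e-5
            )


class TestDiagnostics:
    def _fit_at_truth(self, panels, spec, params):
        design = ssm.build_model(spec, panels)
        return ssm.FitResult(
            spec=spec, params=params, loglik=0.0, K=design.K(), n_eff=design.n_eff,
            aicc=0.0, converged=True, design=design, options=FitOptions(),
            theta=np.zeros(1),
        )

    def test_ljung_box_pvalues_uniform_under_the_model(self):
        rng = np.random.default_rng(25)
        spec = ModelSpec(covariate_names=())
        params = SSMParams(B={}, q={"shared": 0.1}, r=0.2)
        pvals = []
        for _ in range(200):
            base = [make_panel(1, "night", 150, rng, covariates=())]
            panels, _ = ssm.simulate_from_model(spec, base, params, rng)
            report = ssm.residual_diagnostics(
                self._fit_at_truth(panels, spec, params)
            )
            pvals.append(
                report.ljung_box["per_chain"][panels[0].key]["pvalue"]
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_white_innovations_acf_mostly_within_bands(self):
        rng = np.random.default_rng(26)
        spec = ModelSpec(covariate_names=())
        params = SSMParams(B={}, q={"shared": 0.1}, r=0.2)
        counts = []
        for _ in range(10):
            base = [make_panel(1, "night", 200, rng, covariates=())]
            panels, _ = ssm.simulate_from_model(spec, base, params, rng)
            report = ssm.residual_diagnostics(
                self._fit_at_truth(panels, spec, params)
            )
            counts.append(int(np.sum(np.abs(report.acf) < report.acf_band)))
        assert np.mean(counts) >= 18.0

    def test_deterministic_data_gives_zero_residuals(self):
        rng = np.random.default_rng(27)
        T = 40
        c = rng.normal(size=T)
        x = np.cumsum(0.3 * c)
        panel = ChainPanel(
            key=ChainKey(1, "night"),
            day_of_year=np.arange(T),
            response=x,
            covariates={"a": c},
        )
        spec = ModelSpec(covariate_names=("a",))
        params = SSMParams(
            B={"a": 0.3}, q={"shared": 1e-10}, r=1e-10,
            x0={ChainKey(1, "night"): 0.0}, V0=1e-10,
        )
        report = ssm.residual_diagnostics(self._fit_at_truth([panel], spec, params))
        assert np.max(np.abs(report.innovations[panel.key])) < 1e-6

    def test_plot_writes_figure(self, model_panels, tmp_path):
        panels, truth = model_panels
        spec = ModelSpec(covariate_names=("hatchery_diff", "flow_diff", "season"))
        params = SSMParams(B=dict(truth["true_B"]), q={"shared": 0.05}, r=0.1)
        report = ssm.residual_diagnostics(self._fit_at_truth(panels, spec, params))
        out = tmp_path / "diag.png"
        ssm.plot_diagnostics(report, out)
        assert out.stat().st_size > 0


class TestSimulateFromModel:
    def test_preserves_missingness_and_is_seeded(self):
        rng = np.random.default_rng(28)
        base = [make_panel(1, "night", 50, rng, missing=0.2)]
        spec = ModelSpec(covariate_names=("a", "b"))
        params = SSMParams(B={"a": 0.1, "b": -0.2}, q={"shared": 0.05}, r=0.1)
        out1, _ = ssm.simulate_from_model(
            spec, base, params, np.random.default_rng(5)
        )
        out2, _ = ssm.simulate_from_model(
            spec, base, params, np.random.default_rng(5)
        )
        np.testing.assert_array_equal(out1[0].response, out2[0].response)
        np.testing.assert_array_equal(
            np.isnan(out1[0].response), np.isnan(base[0].response)
        )
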