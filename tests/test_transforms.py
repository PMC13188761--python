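"""Covariate-engineering transforms against hand and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from piedpiper import transforms as tr


def brute_trailing_anomaly(values, window):
    out = np.full(len(values), np.nan)
    for i in range(window, len(values)):
        out[i] = values[i] - np.mean(values[i - window : i])
    return out


def brute_interpolate(values):
    values = np.array(values, dtype=float)
    obs = np.isfinite(values)
    out = values.copy()
    idx = np.flatnonzero(obs)
    for i in range(len(values)):
        if np.isfinite(values[i]):
            continue
        left = idx[idx < i]
        right = idx[idx > i]
        if len(left) == 0:
            out[i] = values[right[0]]
        elif len(right) == 0:
            out[i] = values[left[-1]]
        else:
            a, b = left[-1], right[0]
            out[i] = values[a] + (values[b] - values[a]) * (i - a) / (b - a)
    return out


class TestCPUE:
    def make_records(self, rows):
        return pd.DataFrame(
            rows,
            columns=["year", "day_of_year", "period", "origin", "count", "effort_hours"],
        )

    def test_catch_rate_is_count_over_effort_and_gaps_stay_missing(self):
        records = self.make_records(
            [
                (1, 10, "night", "wild", 24, 12.0),
                (1, 10, "night", "hatchery_marked", 6, 12.0),
                (1, 12, "night", "wild", 0, 10.0),
                (1, 12, "night", "hatchery_marked", 0, 10.0),
            ]
        )
        out = tr.compute_cpue(records).set_index("day_of_year")
        assert out.loc[10, "wild_cpue"] == 2.0
        assert out.loc[10, "hatchery_cpue"] == 0.5
        assert out.loc[12, "wild_cpue"] == 0.0
        # day 11 had no trap record: missing, not zero
        assert np.isnan(out.loc[11, "wild_cpue"])

    def test_unmarked_hatchery_fish_count_as_wild_at_the_trap(self):
        records = self.make_records(
            [
                (1, 10, "night", "wild", 10, 10.0),
                (1, 10, "night", "hatchery_marked", 100, 10.0),
                (1, 10, "night", "hatchery_unmarked", 5, 10.0),
            ]
        )
        out = tr.compute_cpue(records)
        assert out.loc[0, "wild_cpue"] == pytest.approx(1.5)
        assert out.loc[0, "hatchery_cpue"] == pytest.approx(10.0)

    def test_non_positive_effort_rejected_with_warning(self):
        records = self.make_records(
            [
                (1, 10, "night", "wild", 5, 10.0),
                (1, 11, "night", "wild", 5, 0.0),
                (1, 12, "night", "wild", 5, 10.0),
            ]
        )
        with pytest.warns(UserWarning, match="non-positive effort"):
            out = tr.compute_cpue(records)
        assert np.isnan(out.set_index("day_of_year").loc[11, "wild_cpue"])


class TestResponseScaling:
    def test_hand_oracle_log_plus_one_then_zscore(self):
        cpue = np.array([0.0, np.e - 1.0, np.e**2 - 1.0])
        scaled, meta = tr.log_scale_response(cpue)
        np.testing.assert_allclose(np.asarray(scaled), [-1.0, 0.0, 1.0], atol=1e-12)
        assert meta["mean"] == pytest.approx(1.0)
        assert meta["sd"] == pytest.approx(1.0)

    def test_standardized_on_non_missing_support(self):
        rng = np.random.default_rng(0)
        cpue = rng.lognormal(1.0, 0.8, size=60)
        cpue[[3, 17, 40]] = np.nan
        scaled, _ = tr.log_scale_response(cpue)
        vals = np.asarray(scaled)[np.isfinite(scaled)]
        assert abs(vals.mean()) < 1e-9
        assert np.std(vals, ddof=1) == pytest.approx(1.0)

    def test_constant_or_sparse_chain_flagged_unusable(self):
        with pytest.raises(tr.ChainUnusableError, match="constant"):
            tr.log_scale_response(np.full(20, 3.0))
        with pytest.raises(tr.ChainUnusableError, match="observed days"):
            tr.log_scale_response(np.array([1.0, np.nan, np.nan, np.nan]))

    def test_double_scaling_rejected(self):
        scaled, _ = tr.log_scale_response(np.array([0.0, 1.0, 3.0, 9.0]))
        with pytest.raises(tr.AlreadyScaledError):
            tr.scale_covariate(scaled, center=True)


class TestHatcheryDifference:
    def test_constant_series_gives_identically_zero_covariate(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled, _ = tr.hatchery_difference(np.full(10, 7.0))
        assert np.all(np.asarray(scaled)[1:] == 0.0)

    def test_scale_only_preserves_sign_and_zero_pattern(self):
        scaled, _ = tr.hatchery_difference(np.array([0.0, 0.0, 10.0, 0.0]))
        vals = np.asarray(scaled)
        assert np.isnan(vals[0])  # missing by construction
        assert vals[1] == 0.0
        assert vals[2] > 0 and vals[3] < 0
        assert vals[2] == pytest.approx(-vals[3])

    def test_unit_sample_sd_on_support(self):
        rng = np.random.default_rng(1)
        scaled, _ = tr.hatchery_difference(rng.gamma(2.0, 3.0, size=50))
        vals = np.asarray(scaled)[1:]
        assert np.std(vals, ddof=1) == pytest.approx(1.0)

    def test_gaps_must_be_interpolated_first(self):
        series = np.array([1.0, np.nan, 3.0])
        with pytest.raises(ValueError, match="gaps"):
            tr.hatchery_difference(series)


class TestTrailingAnomaly:
    def test_constant_series_zero_after_window(self):
        out = tr.trailing_anomaly(np.full(50, 4.2), 32)
        np.testing.assert_allclose(out[32:], 0.0, atol=1e-12)
        assert np.isnan(out[:32]).all()

    def test_linear_ramp_closed_form(self):
        s = 0.7
        values = s * np.arange(100.0)
        out = tr.trailing_anomaly(values, 32)
        np.testing.assert_allclose(out[32:], s * (32 + 1) / 2, rtol=1e-12)

    def test_step_series_first_post_step_anomaly_is_step_height(self):
        values = np.concatenate([np.zeros(40), [10.0]])
        out = tr.trailing_anomaly(values, 32)
        assert out[40] == pytest.approx(10.0)

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(2)
        for window in (1, 5, 32):
            values = rng.normal(size=80)
            np.testing.assert_allclose(
                tr.trailing_anomaly(values, window),
                brute_trailing_anomaly(values, window),
                atol=1e-12,
            )

    @given(shift=st.floats(-50, 50), seed=st.integers(0, 2**16))
    def test_shift_invariance(self, shift, seed):
        values = np.random.default_rng(seed).normal(size=60)
        np.testing.assert_allclose(
            tr.trailing_anomaly(values + shift, 16)[16:],
            tr.trailing_anomaly(values, 16)[16:],
            atol=1e-9,
        )

    def test_window_periodic_series_has_zero_mean_anomaly(self):
        window = 8
        values = np.tile(np.random.default_rng(3).normal(size=window), 10)
        out = tr.trailing_anomaly(values, window)
        assert abs(np.nanmean(out)) < 1e-12


class TestLagDifference:
    @pytest.mark.parametrize(
        "series,expected",
        [
            (np.full(5, 2.0), [np.nan, 0, 0, 0, 0]),
            (2.5 * np.arange(4.0), [np.nan, 2.5, 2.5, 2.5]),
            (np.array([1.0, 4.0, 2.0]), [np.nan, 3.0, -2.0]),
        ],
    )
    def test_examples(self, series, expected):
        np.testing.assert_allclose(tr.lag_difference(series), expected)

    @given(shift=st.floats(-100, 100), seed=st.integers(0, 2**16))
    def test_shift_invariance(self, shift, seed):
        values = np.random.default_rng(seed).normal(size=30)
        np.testing.assert_allclose(
            tr.lag_difference(values + shift)[1:],
            tr.lag_difference(values)[1:],
            atol=1e-9,
        )


class TestMedianMigrationDay:
    def test_single_day_migration(self):
        days = np.arange(140, 160)
        counts = np.zeros(20)
        counts[10] = 500  # all fish on day 150
        assert tr.median_migration_day(days, counts) == 150

    def test_uniform_run_reaches_half_at_fifth_day(self):
        days = np.arange(100, 110)
        assert tr.median_migration_day(days, np.ones(10)) == 104

    def test_symmetric_triangular_pulse(self):
        days = np.arange(120, 161)
        counts = 20.0 - np.abs(days - 140)
        assert tr.median_migration_day(days, counts) == 140

    def test_all_zero_year_is_unusable(self):
        with pytest.raises(tr.ChainUnusableError):
            tr.median_migration_day(np.arange(5), np.zeros(5))

    def test_missing_days_count_zero_fish(self):
        days = np.arange(100, 110)
        counts = np.ones(10)
        counts[:4] = np.nan
        # total 6, half reached at the 3rd observed day
        assert tr.median_migration_day(days, counts) == 106


class TestSeasonCovariate:
    def test_fixed_points_and_sign(self):
        days = np.arange(100, 161)
        scaled, _ = tr.season_covariate(days, 130)
        vals = np.asarray(scaled)
        assert vals[30] == 0.0  # zero on the median day
        assert np.all(vals[:30] > 0)  # positive before
        assert np.all(vals[31:] < 0)  # negative after
        np.testing.assert_allclose(vals, -vals[::-1], atol=1e-12)  # antisymmetric

    def test_symmetric_window_sums_to_zero(self):
        days = np.arange(100, 161)
        scaled, _ = tr.season_covariate(days, 130)
        assert abs(np.sum(np.asarray(scaled))) < 1e-9

    def test_asymmetric_window_sum_sign_follows_median_offset(self):
        days = np.arange(100, 161)
        late_median, _ = tr.season_covariate(days, 140)
        early_median, _ = tr.season_covariate(days, 120)
        assert np.sum(np.asarray(late_median)) > 0
        assert np.sum(np.asarray(early_median)) < 0


class TestScaleCovariate:
    def test_centered_is_zscore(self):
        rng = np.random.default_rng(4)
        scaled, _ = tr.scale_covariate(rng.normal(3.0, 2.0, 40), center=True)
        vals = np.asarray(scaled)
        assert abs(vals.mean()) < 1e-12
        assert np.std(vals, ddof=1) == pytest.approx(1.0)

    def test_scale_only_preserves_sign_and_zeros(self):
        values = np.array([0.0, 1.0, 0.0, 5.0, 2.0])
        scaled, _ = tr.scale_covariate(values, center=False)
        vals = np.asarray(scaled)
        assert np.all(vals >= 0)
        assert vals[0] == 0.0 and vals[2] == 0.0

    def test_zero_variance_emits_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled, meta = tr.scale_covariate(np.full(8, 3.3), center=False)
        assert np.all(np.asarray(scaled) == 0.0)
        assert meta["sd"] == 0.0

    def test_double_scaling_rejected(self):
        scaled, _ = tr.scale_covariate(np.arange(10.0), center=True)
        with pytest.raises(tr.AlreadyScaledError):
            tr.scale_covariate(scaled, center=False)


class TestInterpolateGaps:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([1.0, np.nan, 3.0], [1.0, 2.0, 3.0]),
            ([0.0, np.nan, np.nan, 9.0], [0.0, 3.0, 6.0, 9.0]),
            ([np.nan, 2.0, np.nan], [2.0, 2.0, 2.0]),  # edge extension
        ],
    )
    def test_examples(self, series, expected):
        filled, _ = tr.interpolate_gaps(np.array(series))
        np.testing.assert_allclose(filled, expected, atol=1e-12)

    def test_no_gaps_is_identity_with_zero_fill_fraction(self):
        values = np.arange(10.0)
        filled, report = tr.interpolate_gaps(values)
        np.testing.assert_array_equal(filled, values)
        assert report["fraction_filled"] == 0.0

    @given(seed=st.integers(0, 2**16))
    def test_matches_brute_force_on_random_gap_patterns(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=40)
        gaps = rng.random(40) < 0.3
        gaps[rng.integers(40)] = False  # keep at least one observation
        values[gaps] = np.nan
        filled, report = tr.interpolate_gaps(values)
        np.testing.assert_allclose(filled, brute_interpolate(values), atol=1e-12)
        assert report["n_filled"] == int(gaps.sum())

    def test_entirely_missing_series_errors(self):
        with pytest.raises(ValueError, match="entirely-missing"):
            tr.interpolate_gaps(np.full(5, np.nan))


class TestCollinearityScreen:
    def test_duplicate_covariate_flagged(self):
        x = np.random.default_rng(5).normal(size=100)
        flagged = tr.screen_collinearity({"a": x, "b": x.copy()})
        assert len(flagged) == 1
        assert flagged[0]["pair"] == ("a", "b")
        assert flagged[0]["r"] == pytest.approx(1.0)

    def test_long_independent_noise_not_flagged(self):
        rng = np.random.default_rng(6)
        covs = {k: rng.normal(size=10_000) for k in "abc"}
        assert tr.screen_collinearity(covs) == []

    def test_rounding_boundary_half_up(self):
        assert tr.round_half_up(0.45, 1) == pytest.approx(0.5)
        assert tr.round_half_up(0.44, 1) == pytest.approx(0.4)
        assert tr.round_half_up(-0.45, 1) == pytest.approx(-0.5)

    @given(seed=st.integers(0, 2**16), rho=st.floats(0.0, 0.95))
    def test_flag_rule_matches_rounded_sample_correlation(self, seed, rho):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=200)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=200)
        r = np.corrcoef(x, y)[0, 1]
        flagged = tr.screen_collinearity({"x": x, "y": y})
        assert bool(flagged) == (tr.round_half_up(abs(r), 1) >= 0.5)

    def test_too_few_complete_observations_errors(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            tr.screen_collinearity(
                {"a": np.array([1.0, np.nan, 2.0]), "b": np.array([np.nan, 1.0, 2.0])}
            )
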