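import numpy as np
import pandas as pd
import pytest

from cellsizer import (
    MechanisticMode,
    ModelParams,
    estimate_gamma_derived,
    estimate_gamma_direct,
    estimate_lambda,
    estimate_theta,
    filter_3sd,
    filter_iqr,
    homeostasis_regression,
    make_bins,
    mechanistic_adder_test,
    replicative_growth_mean,
    select_bin_params,
    simulate_lineages,
    sister_asymmetry,
    steadiness_qc,
    summarize,
    theta_gamma_plane,
    weighted_binned_fit,
)
from cellsizer.homeostasis import HomeostasisSummary


class TestFilter3sd:
    def test_injected_outlier_removed(self):
        rng = np.random.default_rng(1)
        vals = np.append(rng.normal(0, 1, 100), 10.0)
        df = pd.DataFrame({"x": vals})
        out, rep = filter_3sd(df, ["x"])
        assert 100 in rep.removed_ids  # the injected value
        assert rep.n_removed <= 2  # at most one extra chance removal

    def test_all_equal_none_removed(self):
        df = pd.DataFrame({"x": np.ones(50)})
        out, rep = filter_3sd(df, ["x"])
        assert rep.n_removed == 0

    def test_within_2sd_none_removed(self):
        rng = np.random.default_rng(2)
        x = np.clip(rng.normal(0, 1, 200), -2, 2)
        out, rep = filter_3sd(pd.DataFrame({"x": x}), ["x"])
        assert rep.n_removed == 0

    def test_idempotent_on_gaussian_data(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"x": rng.normal(0, 1, 300)})
            once, _ = filter_3sd(df, ["x"])
            _, rep2 = filter_3sd(once, ["x"])
            hits += rep2.n_removed == 0
        assert hits >= 9  # spec: >= 95% of seeded runs


class TestFilterIQR:
    def test_hand_computed_band_keeps_all(self):
        # log-values {1..5}: median 3, IQR 2, band [0, 6]
        df = pd.DataFrame(
            {"V_birth": np.exp([1, 2, 3, 4, 5]), "V_mitosis": np.exp([1, 2, 3, 4, 5])}
        )
        out, rep = filter_iqr(df)
        assert rep.n_removed == 0

    def test_hand_computed_outlier_removed(self):
        logs = [1, 2, 3, 4, 5, 10]
        df = pd.DataFrame(
            {"V_birth": np.exp(logs), "V_mitosis": np.exp([3] * 6)}
        )
        out, rep = filter_iqr(df)
        assert rep.n_removed == 1
        assert 5 in rep.removed_ids

    def test_zero_iqr_warns(self):
        df = pd.DataFrame({"V_birth": np.ones(6), "V_mitosis": np.ones(6)})
        with pytest.warns(UserWarning, match="IQR"):
            out, rep = filter_iqr(df)
        assert rep.n_removed == 0  # all values are exactly the median

    def test_rejects_nonpositive(self):
        df = pd.DataFrame({"V_birth": [1.0, -1.0], "V_mitosis": [1.0, 1.0]})
        with pytest.raises(ValueError):
            filter_iqr(df)


class TestSelectBinParams:
    @pytest.mark.parametrize(
        "n,expected",
        [(50, (8, 8)), (100, (10, 15)), (2000, (13, 60)), (6000, (15, 150))],
    )
    def test_microbe_staircase(self, n, expected):
        assert select_bin_params(n, "microbe") == expected

    @pytest.mark.parametrize("n,expected", [(90, (6, 4)), (150, (8, 4)), (5000, (8, 4))])
    def test_animal_policy(self, n, expected):
        assert select_bin_params(n, "animal") == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            select_bin_params(0)
        with pytest.raises(ValueError):
            select_bin_params(10, "fungus")


class TestMakeBins:
    def test_hand_computed_medians(self):
        x = np.arange(1, 11, dtype=float)
        bins = make_bins(x, x, binn=2, minn=1)
        assert list(bins["x_stat"]) == [3.0, 8.0]
        assert list(bins["count"]) == [5, 5]

    def test_all_identical_x_fails(self):
        with pytest.raises(ValueError):
            make_bins(np.ones(20), np.arange(20.0), binn=5, minn=1)

    def test_minn_above_n_fails(self):
        with pytest.raises(ValueError):
            make_bins(np.arange(10.0), np.arange(10.0), binn=2, minn=100)

    def test_rightmost_edge_inclusive(self):
        x = np.array([0.0, 1.0, 2.0])
        bins = make_bins(x, x, binn=2, minn=1)
        assert bins["count"].sum() == 3


class TestWeightedFit:
    def test_exact_line(self):
        bins = pd.DataFrame(
            {"x_stat": [1, 2, 3], "y_stat": [2, 4, 6], "count": [10, 20, 30],
             "y_sd": 0.0}
        )
        fit = weighted_binned_fit(bins)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.p_slope < 1e-10

    def test_closed_form_wls_oracle(self):
        # hand-derived: weights (1,2,1) -> slope 0.5, intercept 1.25
        bins = pd.DataFrame(
            {"x_stat": [0, 1, 2], "y_stat": [1, 2, 2], "count": [1, 2, 1],
             "y_sd": 0.0}
        )
        fit = weighted_binned_fit(bins)
        assert fit.slope == pytest.approx(0.5)
        assert fit.intercept == pytest.approx(1.25)

    def test_equal_weights_reduce_to_ols(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, 6)
        y = 2 * x + rng.normal(0, 1, 6)
        bins = pd.DataFrame({"x_stat": x, "y_stat": y, "count": 7, "y_sd": 0.0})
        fit = weighted_binned_fit(bins)
        b, a = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(b)
        assert fit.intercept == pytest.approx(a)

    def test_two_bins_exact_but_se_missing(self):
        bins = pd.DataFrame(
            {"x_stat": [0, 1], "y_stat": [1, 3], "count": [5, 5], "y_sd": 0.0}
        )
        fit = weighted_binned_fit(bins)
        assert fit.slope == pytest.approx(2.0)
        assert np.isnan(fit.se_slope) and np.isnan(fit.p_slope)

    def test_statsmodels_oracle_fuzz(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        for _ in range(300):
            nb = rng.integers(3, 11)
            x = rng.normal(0, 1, nb)
            while np.unique(x).size < 2:
                x = rng.normal(0, 1, nb)
            y = rng.normal(0, 1, nb)
            w = rng.integers(1, 50, nb).astype(float)
            bins = pd.DataFrame(
                {"x_stat": x, "y_stat": y, "count": w, "y_sd": 0.0}
            )
            fit = weighted_binned_fit(bins)
            model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
            assert fit.slope == pytest.approx(model.params[1], rel=1e-10)
            assert fit.intercept == pytest.approx(model.params[0], rel=1e-10)
            assert fit.se_slope == pytest.approx(model.bse[1], rel=1e-10)
            assert fit.p_slope == pytest.approx(model.pvalues[1], rel=1e-8)
            assert fit.r2 == pytest.approx(model.rsquared, rel=1e-10, abs=1e-12)


class TestEstimators:
    def test_lambda_archetypes(self, sizer_table, adder_table, timer_table):
        for table, target, band in [
            (sizer_table, 1.0, (0.9, 1.1)),
            (adder_table, 0.5, (0.45, 0.55)),
            (timer_table, 0.0, (-0.05, 0.05)),
        ]:
            lam, se, _ = estimate_lambda(table, bin_policy=(8, 4))
            assert band[0] <= lam <= band[1]

    def test_theta_zero_when_tau_independent(self, timer_table):
        theta, se, _ = estimate_theta(timer_table, bin_policy=(8, 4))
        assert abs(theta) < 0.05

    def test_theta_recovery_linear_response(self):
        p = ModelParams.stationary_defaults(theta=0.3, sd_tau=1.0)
        df = simulate_lineages(p, "linear_response", 8, 11, seed=31).head(5000)
        theta, se, _ = estimate_theta(df, bin_policy=(8, 4))
        assert theta == pytest.approx(0.3, abs=0.05)

    def test_theta_of_deterministic_sizer(self, sizer_table):
        theta, se, _ = estimate_theta(sizer_table, bin_policy=(8, 4))
        norm = sizer_table["alpha"].mean() * sizer_table["tau"].mean()
        assert theta * norm == pytest.approx(1.0, abs=0.1)

    def test_gamma_zero_when_alpha_independent(self, timer_table):
        gamma, se, _ = estimate_gamma_direct(timer_table, bin_policy=(8, 4))
        assert abs(gamma) < 0.05

    def test_gamma_recovery_linear_response(self):
        p = ModelParams.stationary_defaults(gamma=0.2, sd_alpha=0.004)
        df = simulate_lineages(p, "linear_response", 8, 11, seed=32).head(5000)
        gamma, se, _ = estimate_gamma_direct(df, bin_policy=(8, 4))
        assert gamma == pytest.approx(0.2, abs=0.05)

    def test_negative_gamma_detected(self):
        p = ModelParams.stationary_defaults(
            theta=0.6, gamma=-0.2, sd_tau=0.8, sd_alpha=0.003
        )
        df = simulate_lineages(p, "linear_response", 8, 11, seed=33).head(5000)
        gamma, se, _ = estimate_gamma_direct(df, bin_policy=(8, 4))
        assert gamma < -0.1

    def test_gamma_derived_arithmetic(self):
        g, se = estimate_gamma_derived(0.5, 0.0, np.log(2))
        assert g == pytest.approx(0.5 / np.log(2))
        g, se = estimate_gamma_derived(0.0, 0.0, np.log(2))
        assert g == 0.0
        with pytest.raises(ValueError):
            estimate_gamma_derived(0.5, 0.1, 0.0)

    def test_gamma_derived_consistent_with_direct(self):
        p = ModelParams.stationary_defaults(
            theta=0.4, gamma=0.3, sd_tau=0.8, sd_alpha=0.003
        )
        df = simulate_lineages(p, "linear_response", 8, 11, seed=34).head(5000)
        lam, se_lam, _ = estimate_lambda(df, bin_policy=(8, 4))
        theta, se_th, _ = estimate_theta(df, bin_policy=(8, 4))
        gd, se_gd, _ = estimate_gamma_direct(df, bin_policy=(8, 4))
        mean_G, se_G = replicative_growth_mean(df)
        gder, se_der = estimate_gamma_derived(lam, theta, mean_G, se_lam, se_th, se_G)
        assert abs(gder - gd) <= 2 * np.hypot(se_der, se_gd)

    def test_mean_G_trivial_cases(self):
        doubling = pd.DataFrame({"V_birth": [1.0, 2.0], "V_mitosis": [2.0, 4.0]})
        g, _ = replicative_growth_mean(doubling)
        assert g == pytest.approx(np.log(2))
        flat = pd.DataFrame({"V_birth": [1.0, 2.0], "V_mitosis": [1.0, 2.0]})
        g, _ = replicative_growth_mean(flat)
        assert g == 0.0

    def test_mean_G_equals_alpha_tau_at_stationarity(self, adder_table):
        g, _ = replicative_growth_mean(adder_table)
        norm = (adder_table["alpha"] * adder_table["tau"]).mean()
        assert g == pytest.approx(norm, rel=1e-9)  # exact by construction
        assert g == pytest.approx(
            adder_table["alpha"].mean() * adder_table["tau"].mean(), rel=0.01
        )

    def test_scale_equivariance(self, adder_table):
        scaled = adder_table.copy()
        for col in ("V_birth", "V_G1S", "V_mitosis"):
            scaled[col] = scaled[col] * 3.7
        lam0, _, _ = estimate_lambda(adder_table, bin_policy=(8, 4))
        lam1, _, _ = estimate_lambda(scaled, bin_policy=(8, 4))
        assert lam1 == pytest.approx(lam0, rel=1e-9)
        th0, _, _ = estimate_theta(adder_table, bin_policy=(8, 4))
        th1, _, _ = estimate_theta(scaled, bin_policy=(8, 4))
        assert th1 == pytest.approx(th0, rel=1e-9)


class TestMechanisticAdder:
    def test_fixed_total_slope_minus_one(self, mech_adder_table):
        fit = mechanistic_adder_test(mech_adder_table, bin_policy=(8, 4))
        assert fit.slope == pytest.approx(-1.0, abs=0.1)
        assert fit.distance_to_minus_one < 0.1

    def test_independent_phase_adders_slope_zero(self):
        rng = np.random.default_rng(41)
        n = 5000
        vb = rng.lognormal(np.log(1300), 0.15, n)
        dv1 = rng.normal(600, 60, n)
        dv2 = rng.normal(700, 70, n)
        df = pd.DataFrame(
            {"V_birth": vb, "V_G1S": vb + dv1, "V_mitosis": vb + dv1 + dv2}
        )
        fit = mechanistic_adder_test(df, bin_policy=(8, 4))
        assert abs(fit.slope) < 0.05

    def test_noiseless_fixed_split_exact_slope(self):
        rng = np.random.default_rng(42)
        vb = rng.lognormal(np.log(1300), 0.15, 500)
        dv1 = rng.normal(400, 80, 500)
        df = pd.DataFrame(
            {"V_birth": vb, "V_G1S": vb + dv1, "V_mitosis": vb + 3 * dv1}
        )
        # dV_SG2 = 2 * dV_G1 exactly
        fit = mechanistic_adder_test(df, bin_policy=(8, 4))
        assert fit.slope == pytest.approx(2.0, rel=1e-9)


class TestSisterAsymmetry:
    def test_symmetric_division_degenerate(self):
        p = ModelParams.stationary_defaults()
        df = simulate_lineages(p, "adder", 6, 10, seed=51).head(2000)
        res = sister_asymmetry(df)
        np.testing.assert_allclose(res.birth_ratios, 1.0)
        assert np.isnan(res.p_value)

    def test_adder_halves_relative_difference(self):
        p = ModelParams.stationary_defaults(division_asymmetry_sd=0.1)
        df = simulate_lineages(
            p, MechanisticMode("adder", mode_sd=0.10 * 1300), 8, 11, seed=52
        ).head(5000)
        res = sister_asymmetry(df)
        ratio = res.mean_reldiff_mitosis / res.mean_reldiff_birth
        assert ratio == pytest.approx(0.5, abs=0.1)
        assert res.p_value < 1e-6

    def test_sizer_erases_birth_asymmetry(self):
        p = ModelParams.stationary_defaults(division_asymmetry_sd=0.1)
        df = simulate_lineages(
            p, MechanisticMode("sizer", mode_sd=0.02 * 2600), 8, 11, seed=53
        ).head(5000)
        res = sister_asymmetry(df)
        assert res.mitosis_ratios.mean() < 1.05
        assert res.birth_ratios.mean() > 1.2

    def test_too_few_pairs(self):
        df = pd.DataFrame(
            {
                "cell_id": [0, 1],
                "sister_id": [1, 0],
                "V_birth": [1.0, 2.0],
                "V_mitosis": [2.0, 3.0],
            }
        )
        with pytest.raises(ValueError):
            sister_asymmetry(df)


class TestSteadiness:
    def test_stationary_not_flagged(self, adder_table):
        rep = steadiness_qc(adder_table, bin_policy=(8, 4))
        assert not rep.drift_flag

    def test_imposed_drift_flagged(self, adder_table):
        drifting = adder_table.copy()
        span = drifting["t_birth"].max() - drifting["t_birth"].min()
        shrink = 1 - 0.15 * (drifting["t_birth"] - drifting["t_birth"].min()) / span
        drifting["V_birth"] = drifting["V_birth"] * shrink
        rep = steadiness_qc(drifting, bin_policy=(8, 4))
        assert rep.drift_flag

    def test_identical_replicates_not_significant(self, adder_table):
        # two literally identical replicates: means equal, t = 0, p = 1
        df = pd.concat(
            [adder_table.assign(replicate="a"), adder_table.assign(replicate="b")],
            ignore_index=True,
        )
        rep = steadiness_qc(df, replicate_col="replicate", bin_policy=(8, 4))
        assert (rep.replicate_tests["p"] > 0.05).all()


class TestThetaGammaPlane:
    def _summary(self, name, lam, theta, gamma, mean_G=np.log(2)):
        return HomeostasisSummary(
            name=name, lam=lam, se_lam=0.01, theta=theta, se_theta=0.01,
            gamma=gamma, se_gamma=0.01, gamma_mode="derived",
            mean_G=mean_G, se_mean_G=0.001,
        )

    def test_adder_datasets_sum_to_half(self):
        s = self._summary("adder", 0.5, 0.4, 0.5 / np.log(2) - 0.4)
        plane = theta_gamma_plane([s])
        row = plane.iloc[0]
        assert row["x_gamma_norm"] + row["y_theta_norm"] == pytest.approx(0.5)

    def test_pure_timer_at_origin(self):
        plane = theta_gamma_plane([self._summary("timer", 0.0, 0.0, 0.0)])
        assert plane.iloc[0]["x_gamma_norm"] == 0.0
        assert plane.iloc[0]["y_theta_norm"] == 0.0

    def test_time_modulated_sizer_on_y_axis(self, sizer_table):
        lam, se_lam, _ = estimate_lambda(sizer_table, bin_policy=(8, 4))
        theta, se_th, _ = estimate_theta(sizer_table, bin_policy=(8, 4))
        mean_G, se_G = replicative_growth_mean(sizer_table)
        gamma, se_g = estimate_gamma_derived(lam, theta, mean_G, se_lam, se_th, se_G)
        s = HomeostasisSummary(
            name="sizer", lam=lam, se_lam=se_lam, theta=theta, se_theta=se_th,
            gamma=gamma, se_gamma=se_g, gamma_mode="derived",
            mean_G=mean_G, se_mean_G=se_G,
        )
        plane = theta_gamma_plane([s])
        row = plane.iloc[0]
        assert row["y_theta_norm"] == pytest.approx(lam, abs=0.15)
        assert abs(row["x_gamma_norm"]) < 0.15
        assert 0.9 <= lam <= 1.1

    def test_summarize_balance_invariant(self, adder_table):
        s = summarize(adder_table, name="adder", bin_policy=(8, 4))
        resid = s.norm_theta + s.norm_gamma - s.lam
        combined = 2 * np.hypot(s.se_theta * s.norm, s.se_gamma * s.norm)
        assert abs(resid) <= max(combined, 0.05)


class TestHomeostasisRegressionDriver:
    def test_adder_added_volume_uncorrelated(self, adder_table):
        df = adder_table.assign(dV=adder_table["V_mitosis"] - adder_table["V_birth"])
        fit = homeostasis_regression(df, "V_birth", "dV", bin_policy=(8, 4))
        assert abs(fit.slope) < 0.06

    def test_log_transform_requires_positive(self):
        df = pd.DataFrame({"x": [-1.0, 1.0] * 10, "y": np.arange(20.0)})
        with pytest.raises(ValueError):
            homeostasis_regression(df, "x", "y", log_x=True)
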