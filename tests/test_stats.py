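import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from photocap import season, stats


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = stats.pearson_r(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        assert stats.pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_hand_summation_oracle(self):
        # dx=(-1.5,-.5,.5,1.5), dy=(-.5,-1.5,1.5,.5): Σdxdy=3, Σdx²=Σdy²=5 → 0.6
        res = stats.pearson_r([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6, abs=1e-12)

    def test_matches_scipy_on_random_vectors(self, rng):
        for _ in range(50):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            res = stats.pearson_r(x, y)
            want_r, want_p = pearsonr(x, y)
            assert res.r == pytest.approx(want_r, abs=1e-12)
            assert res.p_value == pytest.approx(want_p, rel=1e-8)

    def test_zero_variance_names_series(self):
        with pytest.raises(ValueError, match="flat_one"):
            stats.pearson_r([1, 1, 1], [1, 2, 3], x_label="flat_one")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3"):
            stats.pearson_r([1, 2], [3, 4])


class TestCorrelationMatrix:
    def test_symmetric_with_unit_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        rmat, results = stats.correlation_matrix(df)
        assert np.allclose(rmat, rmat.T)
        assert np.allclose(np.diag(rmat), 1.0)
        assert results[("a", "b")].r == results[("b", "a")].r

    def test_two_variable_input(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 2)), columns=["u", "v"])
        rmat, _ = stats.correlation_matrix(df)
        assert rmat.shape == (2, 2)

    def test_stars_thresholds(self):
        assert stats.significance_stars(0.0005) == "***"
        assert stats.significance_stars(0.005) == "**"
        assert stats.significance_stars(0.04) == "*"
        assert stats.significance_stars(0.2) == ""


def _trait_table(rng, n=29):
    chl = rng.uniform(35, 75, n)
    car = rng.uniform(8, 14, n)
    n_area = rng.uniform(1.2, 2.1, n)  # g m⁻²
    return pd.DataFrame(
        {"chl_area_ug_cm2": chl, "car_area_ug_cm2": car, "n_area_g_m2": n_area}
    )


class TestLinearModels:
    def test_exact_recovery_of_generating_plane(self, rng):
        # capacity generated exactly as a plane in (chl, car) is recovered exactly
        df = _trait_table(rng)
        df["vcmax25"] = 1.99 * df.chl_area_ug_cm2 + 3.13 * df.car_area_ug_cm2 - 43.51
        m = stats.fit_linear_model(df, "vcmax25", ["chl_area_ug_cm2", "car_area_ug_cm2"])
        assert m.coefficients["chl_area_ug_cm2"] == pytest.approx(1.99, abs=1e-8)
        assert m.coefficients["car_area_ug_cm2"] == pytest.approx(3.13, abs=1e-8)
        assert m.coefficients["intercept"] == pytest.approx(-43.51, abs=1e-8)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_identity_regression(self, rng):
        df = _trait_table(rng)
        df["vcmax25"] = df["chl_area_ug_cm2"]
        m = stats.fit_linear_model(df, "vcmax25", ["chl_area_ug_cm2"])
        assert m.coefficients["chl_area_ug_cm2"] == pytest.approx(1.0, abs=1e-10)
        assert m.coefficients["intercept"] == pytest.approx(0.0, abs=1e-8)
        assert m.r_squared == pytest.approx(1.0)

    def test_pearson_squared_equals_simple_r2(self, rng):
        df = _trait_table(rng)
        df["vcmax25"] = 2.0 * df.chl_area_ug_cm2 + rng.normal(0, 8, len(df))
        m = stats.fit_linear_model(df, "vcmax25", ["chl_area_ug_cm2"])
        r = stats.pearson_r(df.chl_area_ug_cm2, df.vcmax25).r
        assert m.r_squared == pytest.approx(r * r, abs=1e-10)

    def test_nested_model_r2_never_exceeds_superset(self, rng):
        df = _trait_table(rng)
        df["vcmax25"] = (
            10 * df.n_area_g_m2 + 1.5 * df.chl_area_ug_cm2 + rng.normal(0, 5, len(df))
        )
        small = stats.fit_linear_model(df, "vcmax25", ["chl_area_ug_cm2"])
        big = stats.fit_linear_model(
            df, "vcmax25", ["chl_area_ug_cm2", "car_area_ug_cm2", "n_area_g_m2"]
        )
        assert big.r_squared >= small.r_squared - 1e-12

    def test_rank_deficient_design_reported(self, rng):
        df = _trait_table(rng)
        df["dup"] = df["chl_area_ug_cm2"]
        df["vcmax25"] = df["chl_area_ug_cm2"] * 2
        with pytest.raises(ValueError, match="collinear"):
            stats.fit_linear_model(df, "vcmax25", ["chl_area_ug_cm2", "dup"])

    def test_too_few_rows_rejected(self, rng):
        df = _trait_table(rng, n=3)
        df["vcmax25"] = 1.0 * df.chl_area_ug_cm2
        with pytest.raises(ValueError, match="too few"):
            stats.fit_linear_model(
                df, "vcmax25", ["chl_area_ug_cm2", "car_area_ug_cm2", "n_area_g_m2"]
            )

    def test_noisy_recovery_unbiased(self, rng):
        # three-predictor truth refit over replicates: estimates center on truth
        truth = dict(n_area_g_m2=22.30, chl_area_ug_cm2=1.26, car_area_ug_cm2=6.18)
        est = []
        df0 = _trait_table(rng)
        mean = (
            22.30 * df0.n_area_g_m2 + 1.26 * df0.chl_area_ug_cm2 + 6.18 * df0.car_area_ug_cm2 - 71.99
        )
        for _ in range(200):
            df = df0.copy()
            df["vcmax25"] = mean + rng.normal(0, 5, len(df))
            m = stats.fit_linear_model(df, "vcmax25", list(truth))
            est.append([m.coefficients[k] for k in truth])
        est = np.array(est)
        se = est.std(axis=0) / np.sqrt(len(est))
        for j, k in enumerate(truth):
            assert abs(est[:, j].mean() - truth[k]) < 3 * se[j] + 1e-9


class TestModelSuite:
    def test_suite_enumerates_ten_models(self, rng):
        df = _trait_table(rng)
        df["vcmax25"] = 1.99 * df.chl_area_ug_cm2 + 3.13 * df.car_area_ug_cm2 - 43.51
        df["jmax25"] = 1.7 * df["vcmax25"]
        models = stats.model_suite(df)
        assert len(models) == 10
        assert sum(m.response == "jmax25" for m in models) == 3

    def test_full_model_attains_max_r2_on_plane_data(self, rng):
        df = _trait_table(rng)
        df["vcmax25"] = (
            22.30 * df.n_area_g_m2 + 1.26 * df.chl_area_ug_cm2 + 6.18 * df.car_area_ug_cm2 - 71.99
        )
        df["jmax25"] = 1.7 * df["vcmax25"]
        models = stats.model_suite(df)
        full = [m for m in models if len(m.predictors) == 3][0]
        assert full.r_squared == pytest.approx(max(m.r_squared for m in models), abs=1e-12)

    def test_single_driver_makes_extra_predictors_redundant(self, rng):
        df = _trait_table(rng)
        df["vcmax25"] = 1.99 * df.chl_area_ug_cm2 + rng.normal(0, 0.5, len(df))
        df["jmax25"] = 1.7 * df["vcmax25"]
        models = {
            "+".join(m.predictors): m
            for m in stats.model_suite(df)
            if m.response == "vcmax25"
        }
        r2_chl = models["chl_area_ug_cm2"].r_squared
        r2_full = models["n_area_g_m2+chl_area_ug_cm2+car_area_ug_cm2"].r_squared
        assert r2_full - r2_chl < 0.05


class TestRFImportance:
    def test_noise_predictor_near_zero_importance(self, rng):
        base = _trait_table(rng, n=60)
        base["noise"] = rng.normal(size=60)
        base["vcmax25"] = 2.0 * base.chl_area_ug_cm2 + rng.normal(0, 4, 60)
        vals = []
        for s in range(10):
            imp = stats.rf_importance(
                base,
                predictors=("chl_area_ug_cm2", "noise"),
                settings=stats.RFSettings(n_trees=200, seed=s),
            )
            vals.append(imp.inc_mse["noise"])
        assert abs(np.mean(vals)) < 2.0

    def test_informative_predictor_dominates(self, rng):
        df = _trait_table(rng, n=60)
        df["noise"] = rng.normal(size=60)
        df["vcmax25"] = 2.0 * df.chl_area_ug_cm2 + rng.normal(0, 4, 60)
        imp = stats.rf_importance(
            df,
            predictors=("chl_area_ug_cm2", "noise"),
            settings=stats.RFSettings(n_trees=200, seed=0),
        )
        assert imp.inc_mse["chl_area_ug_cm2"] > 10 * max(imp.inc_mse["noise"], 1.0)
        assert imp.ranking()[0] == "chl_area_ug_cm2"

    def test_deterministic_given_seed(self, rng):
        df = _trait_table(rng, n=40)
        df["vcmax25"] = 2.0 * df.chl_area_ug_cm2 + rng.normal(0, 4, 40)
        kw = dict(
            predictors=("chl_area_ug_cm2", "car_area_ug_cm2"),
            settings=stats.RFSettings(n_trees=100, seed=5),
        )
        a = stats.rf_importance(df, **kw)
        b = stats.rf_importance(df, **kw)
        assert a.inc_mse == b.inc_mse

    def test_duplicated_predictor_importance_split_nonnegative(self, rng):
        df = _trait_table(rng, n=60)
        df["chl_copy"] = df["chl_area_ug_cm2"]
        df["vcmax25"] = 2.0 * df.chl_area_ug_cm2 + rng.normal(0, 2, 60)
        imp = stats.rf_importance(
            df,
            predictors=("chl_area_ug_cm2", "chl_copy", "car_area_ug_cm2"),
            settings=stats.RFSettings(n_trees=300, seed=1),
        )
        assert imp.inc_mse["chl_area_ug_cm2"] >= 0
        assert imp.inc_mse["chl_copy"] >= 0

    def test_too_few_rows_rejected(self, rng):
        df = _trait_table(rng, n=5)
        df["vcmax25"] = df.chl_area_ug_cm2
        with pytest.raises(ValueError, match="minimum"):
            stats.rf_importance(df, predictors=("chl_area_ug_cm2",))


class TestSeasonalChanges:
    def _samples(self, means_by_doy):
        rows = []
        for doy, v in means_by_doy.items():
            rows.append({"doy": doy, "vcmax25": float(v)})
        return pd.DataFrame(rows)

    def test_rise_relative_to_earlier(self):
        s = stats.seasonal_changes(
            self._samples({92: 100.0, 126: 162.0}), 92, 126, ["vcmax25"]
        )
        assert s.changes["vcmax25"].pct_rel_earlier == pytest.approx(62.0)

    def test_equal_means_give_zero_under_both(self):
        s = stats.seasonal_changes(
            self._samples({92: 50.0, 126: 50.0}), 92, 126, ["vcmax25"]
        )
        ch = s.changes["vcmax25"]
        assert ch.pct_rel_earlier == 0.0 and ch.pct_rel_later == 0.0

    def test_steep_decline_exceeds_100_only_relative_to_later(self):
        # 133.46 → 46: a "190% decline" exists only relative to the later mean
        s = stats.seasonal_changes(
            self._samples({126: 133.46, 147: 46.0}), 126, 147, ["vcmax25"]
        )
        ch = s.changes["vcmax25"]
        assert ch.pct_rel_later == pytest.approx(-190.13, abs=0.01)
        assert -100.0 < ch.pct_rel_earlier < 0.0

    def test_missing_doy_rejected(self):
        with pytest.raises(ValueError, match="DOY"):
            stats.seasonal_changes(self._samples({92: 1.0}), 92, 126, ["vcmax25"])

    def test_peak_reported(self):
        s = stats.seasonal_changes(
            self._samples({92: 80.0, 126: 133.0, 147: 46.0}), 92, 147, ["vcmax25"]
        )
        assert s.changes["vcmax25"].peak_doy == 126
        assert s.changes["vcmax25"].peak_value == pytest.approx(133.0)


class TestSeasonStatsIntegration:
    def test_pooled_correlation_ordering_under_calibrated_couplings(self, design):
        # pooled over replicate seasons the trait–capacity correlation ordering
        # of the calibrated generator holds: Chl > Car > N
        frames = []
        for s in range(20):
            cfg = season.TraitTrajectoryConfig(rng_seed=s)
            frames.append(season.truths_to_frame(season.simulate_season(design, cfg)))
        df = pd.concat(frames)
        df["n_area_g_m2"] = df["n_area_ug_cm2"] / 100.0
        r2 = {
            p: stats.fit_linear_model(df, "vcmax25", [p]).r_squared
            for p in ("chl_area_ug_cm2", "car_area_ug_cm2", "n_area_g_m2")
        }
        assert r2["chl_area_ug_cm2"] > r2["car_area_ug_cm2"] > r2["n_area_g_m2"]

    def test_strong_chl_coupling_beats_weak_n_coupling(self, design):
        cfg = season.ordered_coupling_config(rng_seed=11)
        df = season.truths_to_frame(season.simulate_season(design, cfg))
        r_chl = stats.pearson_r(df.vcmax25, df.chl_area_ug_cm2).r
        r_n = stats.pearson_r(df.vcmax25, df.n_area_ug_cm2).r
        assert r_chl > r_n
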