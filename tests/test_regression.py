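"""Model-family fitting, goodness of fit, selection, grid prediction."""

import numpy as np
import pandas as pd
import pytest

import hazegrid as hg
from hazegrid.regression import FAMILIES, evaluate_family

COEFFS = {
    "linear": (3.0, 2.0),
    "logarithmic": (50.632, 14.94),
    "exponential": (13.855, 0.8954),
    "power": (57.754, 0.6976),
    "quadratic": (10.896, 164.79, -125.54),
    "cubic": (19.342, 96.537, 28.489, -105.07),
}


class TestMinMax:
    def test_basic_example(self):
        np.testing.assert_allclose(hg.minmax_normalize([2.0, 4.0, 6.0]),
                                   [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self):
        v = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(hg.minmax_normalize(v), v)

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            v = rng.random(20)
            np.testing.assert_array_equal(np.argsort(v),
                                          np.argsort(hg.minmax_normalize(v)))

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            hg.minmax_normalize([1.0, 1.0])


class TestFitFamily:
    @pytest.mark.parametrize("family", sorted(FAMILIES))
    def test_noise_free_recovery_to_eight_digits(self, family):
        x = np.linspace(0.05, 1.4, 60)
        truth = COEFFS[family]
        y = evaluate_family(family, truth, x)
        m = hg.fit_family(family, x, y)
        np.testing.assert_allclose(m.coefficients, truth, rtol=1e-8)
        r2, _ = hg.goodness(m, x, y)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_domain_guards(self):
        x = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match="x > 0"):
            hg.fit_family("power", x, y)
        with pytest.raises(ValueError, match="x > 0"):
            hg.fit_family("logarithmic", x, y)
        with pytest.raises(ValueError, match="y > 0"):
            hg.fit_family("exponential", x + 1.0, y - 3.0)

    def test_unknown_family_and_tiny_sample(self):
        with pytest.raises(ValueError, match="family"):
            hg.fit_family("spline", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="samples"):
            hg.fit_family("cubic", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_singular_design_rejected(self):
        x = np.full(10, 2.0)
        with pytest.raises(ValueError, match="singular|constant|samples"):
            hg.fit_family("linear", x, np.arange(10.0))

    def test_normalize_x_freezes_build_bounds(self):
        x = np.linspace(1.0, 3.0, 30)
        y = 3.0 + 2.0 * x
        m = hg.fit_family("linear", x, y, normalize_x=True)
        assert m.x_bounds == (1.0, 3.0)
        # prediction at raw x uses the frozen transform
        assert m.predict(np.array([2.0]))[0] == pytest.approx(7.0)

    def test_refine_option_matches_transform_fit_on_clean_data(self):
        x = np.linspace(0.1, 1.5, 40)
        y = evaluate_family("power", (57.754, 0.6976), x)
        a = hg.fit_family("power", x, y)
        b = hg.fit_family("power", x, y, refine=True)
        np.testing.assert_allclose(a.coefficients, b.coefficients, rtol=1e-6)


class TestGoodness:
    def test_perfect_and_mean_model(self):
        x = np.linspace(0.0, 1.0, 20)
        y = 3.0 + 2.0 * x
        perfect = hg.FittedModel("linear", (3.0, 2.0))
        assert hg.goodness(perfect, x, y)[0] == pytest.approx(1.0)
        mean_model = hg.FittedModel("linear", (float(y.mean()), 0.0))
        assert hg.goodness(mean_model, x, y)[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_five_point_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.8])
        m = hg.fit_family("linear", x, y)
        # brute-force arithmetic on the definition
        yhat = m.coefficients[0] + m.coefficients[1] * x
        sst = np.sum((y - y.mean()) ** 2)
        sse = np.sum((y - yhat) ** 2)
        ssr = np.sum((yhat - y.mean()) ** 2)
        r2, f = hg.goodness(m, x, y)
        assert r2 == pytest.approx(1 - sse / sst, abs=1e-12)
        # explained/total form coincides for an OLS linear fit
        assert r2 == pytest.approx(ssr / sst, abs=1e-12)
        n, p = 5, 1
        assert f == pytest.approx((r2 / p) / ((1 - r2) / (n - p - 1)), abs=1e-9)

    def test_r2_equals_squared_pearson_for_linear_fits(self):
        rng = np.random.default_rng(4)
        x = rng.random(60)
        y = 2.0 + 1.5 * x + rng.normal(0, 0.3, 60)
        m = hg.fit_family("linear", x, y)
        r2, _ = hg.goodness(m, x, y)
        assert r2 == pytest.approx(hg.pearson_r(m.predict(x), y) ** 2, abs=1e-12)
        assert r2 <= 1.0

    def test_r2_bounded_above_for_nonlinear_backtransforms(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.05, 1.5, 80)
        y = 57.754 * x ** 0.6976 * np.exp(rng.normal(0, 0.2, 80))
        for family in sorted(FAMILIES):
            m = hg.fit_family(family, x, y)
            assert hg.goodness(m, x, y)[0] <= 1.0

    def test_zero_total_sum_of_squares_rejected(self):
        m = hg.FittedModel("linear", (1.0, 0.0))
        with pytest.raises(ValueError, match="constant"):
            hg.goodness(m, np.arange(5.0), np.ones(5))


class TestRMSE:
    def test_zero_and_symmetric_residuals(self):
        m = hg.FittedModel("linear", (0.0, 1.0))
        x = np.array([1.0, 2.0])
        assert hg.rmse(m, x, x) == 0.0
        assert hg.rmse(m, x, x + np.array([3.0, -3.0])) == pytest.approx(3.0)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(6)
        x, y = rng.random(100), rng.random(100)
        m = hg.fit_family("linear", x, y)
        resid = y - m.predict(x)
        assert hg.rmse(m, x, y) == pytest.approx(
            np.sqrt(np.sum(resid ** 2) / len(x)), abs=1e-12)


class TestSplit:
    def _pairs(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        dates = pd.date_range("2016-03-01", periods=n).strftime("%Y-%m-%d")
        x = rng.uniform(0.1, 1.4, n)
        y = 57.754 * x ** 0.6976 + rng.normal(0, 3, n)
        return pd.DataFrame({"date": dates, "season": "spring", "x": x, "y": y,
                             "station_id": "s"})

    def test_chronological_split_with_fixed_counts(self):
        pairs = self._pairs()
        splits = hg.split_by_season(pairs, build_counts={"spring": 82},
                                    outlier_rule=None)
        sp = splits["spring"]
        assert len(sp.build) == 82 and len(sp.verify) == 38
        assert sp.build["date"].max() <= sp.verify["date"].min()

    def test_shuffled_input_gives_identical_split(self):
        pairs = self._pairs()
        shuffled = pairs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = hg.split_by_season(pairs, outlier_rule=None)["spring"]
        b = hg.split_by_season(shuffled, outlier_rule=None)["spring"]
        pd.testing.assert_frame_equal(a.build, b.build)
        pd.testing.assert_frame_equal(a.verify, b.verify)

    def test_outlier_rule_eliminates_planted_anomalies(self):
        pairs = self._pairs()
        pairs.loc[pairs.index[-3:], "y"] += 200.0  # gross anomalies in verify
        splits = hg.split_by_season(pairs, build_counts={"spring": 82})
        sp = splits["spring"]
        assert len(sp.eliminated) >= 3
        assert len(sp.verify) + len(sp.eliminated) == 38

    def test_disabled_rule_keeps_everything(self):
        pairs = self._pairs()
        sp = hg.split_by_season(pairs, outlier_rule=None)["spring"]
        assert len(sp.eliminated) == 0

    def test_too_small_season_rejected(self):
        with pytest.raises(ValueError, match="too few"):
            hg.split_by_season(self._pairs(n=8))


class TestSelection:
    def test_single_candidate_returned(self):
        x = np.linspace(0.1, 1.0, 30)
        y = 3 + 2 * x
        m = hg.fit_family("linear", x, y)
        assert hg.select_model([m], x, y) is m

    def test_parsimony_tie_break(self):
        x = np.linspace(0.1, 1.0, 40)
        y = 3.0 + 2.0 * x
        lin = hg.fit_family("linear", x, y)
        cub = hg.fit_family("cubic", x, y)
        assert hg.select_model([cub, lin], x, y).family == "linear"

    def test_generating_family_selected_under_noise(self):
        """Power-generated seasonal samples, 10% noise: power wins ≥ 90/100."""
        wins = 0
        n, n_build = 400, 280
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.clip(np.exp(rng.normal(np.log(0.5), 0.7, n)), 0.02, 1.95)
            s2 = np.log1p(0.10 ** 2)
            y = 57.754 * x ** 0.6976 * np.exp(rng.normal(-s2 / 2, np.sqrt(s2), n))
            cands = hg.fit_all_families(x[:n_build], y[:n_build])
            best = hg.select_model(cands, x[n_build:], y[n_build:])
            wins += best.family == "power"
        assert wins >= 90

    def test_no_candidates_rejected(self):
        with pytest.raises(ValueError):
            hg.select_model([], [1.0], [1.0])


class TestPredictGrid:
    def test_power_identity_at_unit_aod(self):
        m = hg.FittedModel("power", (78.184, 0.4069))
        grid = np.array([[1.0, np.nan], [0.0, 0.5]])
        out = hg.predict_grid(m, grid)
        assert out[0, 0] == pytest.approx(78.184)
        assert np.isnan(out[0, 1])      # nodata propagates
        assert np.isnan(out[1, 0])      # x = 0 outside the power domain
        assert out[1, 1] > 0

    def test_exponential_at_zero_aod(self):
        m = hg.FittedModel("exponential", (13.855, 0.8954))
        out = hg.predict_grid(m, np.array([[0.0]]))
        assert out[0, 0] == pytest.approx(13.855)

    def test_negative_predictions_floored(self):
        m = hg.FittedModel("linear", (-10.0, 1.0))
        out = hg.predict_grid(m, np.array([[0.5]]))
        assert out[0, 0] == 0.0

    def test_all_nodata_grid(self):
        m = hg.FittedModel("linear", (1.0, 1.0))
        out = hg.predict_grid(m, np.full((3, 3), np.nan))
        assert np.isnan(out).all()


def test_model_json_round_trip(tmp_path):
    m = hg.FittedModel("power", (57.754, 0.6976), "spring",
                       {"r2_build": 0.51}, (0.1, 1.5))
    back = hg.FittedModel.from_json(m.to_json())
    assert back.family == m.family
    assert back.coefficients == m.coefficients
    assert back.x_bounds == m.x_bounds
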