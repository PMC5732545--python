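import numpy as np
import pandas as pd
import pytest

from priorimap.abundance import (
    AbundanceModel,
    AdjustmentFit,
    apply_adjustment,
    fit_abundance,
    fit_adjustment,
    predict_abundance,
    r_squared,
    rmse,
    split_train_test,
    stepwise_select,
)
from priorimap.grid import Grid
from priorimap.layers import PredictorStack


def count_samples(rng, n=400, n_noise=6, signal=True):
    """Counts driven (or not) by two predictors among several candidates."""
    data = {f"x{i}": rng.uniform(0, 1, n) for i in range(2 + n_noise)}
    df = pd.DataFrame(data)
    if signal:
        df["count"] = np.round(30 * df["x0"] + 20 * (df["x1"] > 0.5)).astype(int)
    else:
        df["count"] = rng.integers(0, 30, n)
    return df


class TestSplitTrainTest:
    def test_sizes_n10(self):
        df = pd.DataFrame({"a": range(10)})
        train, test = split_train_test(df, seed=0)
        assert (len(train), len(test)) == (8, 2)

    def test_sizes_n94(self):
        df = pd.DataFrame({"a": range(94)})
        train, test = split_train_test(df, seed=0)
        assert (len(train), len(test)) == (75, 19)

    def test_partition_is_disjoint_and_exhaustive(self):
        df = pd.DataFrame({"a": range(37)})
        train, test = split_train_test(df, seed=3)
        together = sorted(train["a"].tolist() + test["a"].tolist())
        assert together == list(range(37))

    def test_deterministic(self):
        df = pd.DataFrame({"a": range(20)})
        t1, _ = split_train_test(df, seed=5)
        t2, _ = split_train_test(df, seed=5)
        assert t1["a"].tolist() == t2["a"].tolist()

    def test_bad_fraction(self):
        df = pd.DataFrame({"a": range(10)})
        with pytest.raises(ValueError):
            split_train_test(df, train_fraction=1.0)


class TestMetrics:
    def test_rmse_zero_on_identical(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_rmse_hand_example(self):
        assert rmse([0, 4], [2, 2]) == 2.0

    def test_rmse_matches_formula_oracle(self):
        rng = np.random.default_rng(40)
        for _ in range(20):
            obs = rng.normal(size=30)
            pred = rng.normal(size=30)
            oracle = np.sqrt(np.mean((obs - pred) ** 2))
            assert rmse(obs, pred) == pytest.approx(oracle, abs=1e-12)

    def test_rmse_permutation_invariant(self):
        rng = np.random.default_rng(41)
        obs = rng.normal(size=25)
        pred = rng.normal(size=25)
        perm = rng.permutation(25)
        assert rmse(obs[perm], pred[perm]) == pytest.approx(rmse(obs, pred))

    def test_r_squared_perfect_linear(self):
        obs = np.arange(10.0)
        assert r_squared(obs, 2 * obs + 3) == pytest.approx(1.0)

    def test_r_squared_independent_near_zero(self):
        rng = np.random.default_rng(42)
        obs = rng.normal(size=1000)
        pred = rng.normal(size=1000)
        assert r_squared(obs, pred) < 0.05

    def test_r_squared_matches_covariance_oracle(self):
        rng = np.random.default_rng(43)
        obs = rng.normal(size=50)
        pred = obs * 0.5 + rng.normal(size=50)
        cov = np.mean((obs - obs.mean()) * (pred - pred.mean()))
        oracle = cov**2 / (obs.var() * pred.var())
        assert r_squared(obs, pred) == pytest.approx(oracle)

    def test_r_squared_sse_variant(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.1, 1.9, 3.2, 3.8])
        sst = np.sum((obs - obs.mean()) ** 2)
        sse = np.sum((obs - pred) ** 2)
        assert r_squared(obs, pred, method="sse") == pytest.approx(1 - sse / sst)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            r_squared([1, 1, 1], [1, 2, 3])


class TestStepwiseSelect:
    def test_recovers_driving_pair(self):
        hits = 0
        for seed in range(20):
            df = count_samples(np.random.default_rng(seed), n=300)
            selected = stepwise_select(df, [f"x{i}" for i in range(8)],
                                       n_trees=100, seed=seed)
            if {"x0", "x1"} <= set(selected):
                hits += 1
        assert hits >= 18

    def test_null_response_selects_little(self):
        small = 0
        for seed in range(20):
            df = count_samples(np.random.default_rng(100 + seed), n=300, signal=False)
            selected = stepwise_select(df, [f"x{i}" for i in range(8)],
                                       n_trees=100, seed=seed)
            if len(selected) <= 2:
                small += 1
        assert small >= 15

    def test_single_informative_candidate_returned(self):
        df = count_samples(np.random.default_rng(7), n=300)
        selected = stepwise_select(df, ["x0"], n_trees=100, seed=7)
        assert selected == ["x0"]

    def test_empty_candidates_raise(self):
        df = count_samples(np.random.default_rng(0), n=50)
        with pytest.raises(ValueError):
            stepwise_select(df, [], n_trees=50, seed=0)


class TestFitAbundance:
    def test_monotone_signal_high_oob_r2(self):
        rng = np.random.default_rng(50)
        df = pd.DataFrame({"x0": rng.uniform(0, 1, 500), "x1": rng.uniform(0, 1, 500)})
        df["count"] = np.round(50 * df["x0"]).astype(int)
        model = fit_abundance(df, ["x0", "x1"], n_trees=300, seed=50)
        assert model.oob_r_squared_ >= 0.8

    def test_shuffled_response_low_oob_r2(self):
        rng = np.random.default_rng(51)
        df = pd.DataFrame({"x0": rng.uniform(0, 1, 500), "x1": rng.uniform(0, 1, 500)})
        df["count"] = rng.permutation(np.round(50 * df["x0"]).astype(int))
        model = fit_abundance(df, ["x0", "x1"], n_trees=300, seed=51)
        assert model.oob_r_squared_ <= 0.1

    def test_constant_counts_raise(self):
        rng = np.random.default_rng(52)
        df = pd.DataFrame({"x0": rng.uniform(0, 1, 50), "count": 5})
        with pytest.raises(ValueError):
            fit_abundance(df, ["x0"], n_trees=50, seed=0)

    def test_empty_selection_raises(self):
        df = count_samples(np.random.default_rng(0), n=50)
        with pytest.raises(ValueError):
            fit_abundance(df, [], n_trees=50, seed=0)


class TestPredictAbundance:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(60)
        df = count_samples(rng, n=300, n_noise=0)
        model = fit_abundance(df, ["x0", "x1"], n_trees=150, seed=60)
        layers = {}
        for name in ("x0", "x1"):
            nodata = np.zeros((9, 11), dtype=bool)
            nodata[2, 3] = True
            layers[name] = Grid(values=rng.uniform(0, 1, (9, 11)),
                                pixel_size=30.0, nodata=nodata)
        return model, PredictorStack(layers)

    def test_matches_extract_then_predict_oracle(self, fitted):
        model, stack = fitted
        ra = predict_abundance(model, stack)
        X, valid = stack.as_matrix(["x0", "x1"])
        assert np.allclose(ra.values[valid], model.predict_mean(X))

    def test_nodata_propagates(self, fitted):
        model, stack = fitted
        ra = predict_abundance(model, stack)
        assert ra.nodata[2, 3]

    def test_constant_landscape_gives_constant_surface(self, fitted):
        model, _ = fitted
        layers = {
            "x0": Grid(values=np.full((5, 5), 0.4), pixel_size=30.0),
            "x1": Grid(values=np.full((5, 5), 0.6), pixel_size=30.0),
        }
        ra = predict_abundance(model, PredictorStack(layers))
        assert np.allclose(ra.values, ra.values[0, 0])

    def test_missing_layer_raises(self, fitted):
        model, stack = fitted
        with pytest.raises(ValueError):
            predict_abundance(model, PredictorStack({"x0": stack["x0"]}))


class TestAdjustment:
    def test_exact_linear_fit(self):
        fit = fit_adjustment([5, 7, 9], [1, 2, 3])
        assert fit.A == pytest.approx(2.0, abs=1e-12)
        assert fit.B == pytest.approx(3.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_slope_for_constant_obs(self):
        fit = fit_adjustment([4, 4, 4], [1, 2, 3])
        assert fit.A == 0.0 and fit.B == 4.0

    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(70)
        pred = rng.uniform(0, 30, 1000)
        obs = 2.0 * pred + 3.0 + rng.normal(0, 0.2, 1000)
        fit = fit_adjustment(obs, pred)
        assert abs(fit.A - 2.0) / 2.0 < 0.02
        assert abs(fit.B - 3.0) / 3.0 < 0.02
        # closed-form OLS oracle
        A_hat = np.cov(pred, obs, ddof=1)[0, 1] / np.var(pred, ddof=1)
        B_hat = obs.mean() - A_hat * pred.mean()
        assert fit.A == pytest.approx(A_hat)
        assert fit.B == pytest.approx(B_hat)

    def test_degenerate_prediction_variance_raises(self):
        with pytest.raises(ValueError):
            fit_adjustment([1, 2, 3], [5, 5, 5])

    def test_apply_identity(self):
        g = Grid(values=np.abs(np.random.default_rng(0).normal(size=(4, 4))),
                 pixel_size=30.0)
        out = apply_adjustment(AdjustmentFit(A=1.0, B=0.0, r_squared=1.0), g)
        assert np.allclose(out.values, g.values)

    def test_apply_affine_and_clip(self):
        g = Grid(values=np.array([[10.0, -5.0]]), pixel_size=30.0)
        out = apply_adjustment(AdjustmentFit(A=2.0, B=3.0, r_squared=1.0), g)
        assert out.values[0, 0] == 23.0
        assert out.values[0, 1] == 0.0  # 2*(-5)+3 = -7 -> clipped

    def test_apply_propagates_nodata(self):
        nodata = np.array([[False, True]])
        g = Grid(values=np.array([[1.0, 2.0]]), pixel_size=30.0, nodata=nodata)
        out = apply_adjustment(AdjustmentFit(A=1.0, B=1.0, r_squared=1.0), g)
        assert bool(out.nodata[0, 1])
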