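import numpy as np
import pandas as pd
import pytest

from priorimap.grid import Grid
from priorimap.layers import PredictorStack
from priorimap.occurrence import (
    OccurrenceModel,
    fit_occurrence,
    partial_dependence,
    predict_rio,
    roc_auc,
    sample_pseudo_absences,
    variable_importance,
)


def make_samples(rng, n=500, signal="step"):
    """Tabular presence/background samples with one driving predictor."""
    x0 = rng.uniform(0, 1, n)
    x1 = rng.uniform(0, 1, n)
    x2 = rng.uniform(0, 1, n)
    if signal == "step":
        presence = (x0 > 0.5).astype(int)
    else:
        presence = rng.integers(0, 2, n)
    return pd.DataFrame({"x0": x0, "x1": x1, "x2": x2, "presence": presence})


class TestSamplePseudoAbsences:
    def test_exact_n_in_mask(self):
        mask = Grid(values=np.ones((60, 40)), pixel_size=30.0)
        obs = sample_pseudo_absences(mask, 500, seed=1)
        assert len(obs) == 500
        assert np.all(obs.presence == 0) and np.all(obs.count == 0)
        row, col = mask.index_of(obs.x, obs.y)
        assert np.all((row >= 0) & (row < 60) & (col >= 0) & (col < 40))

    def test_exhaustion_selects_every_pixel(self):
        mask = Grid(values=np.ones((5, 5)), pixel_size=30.0)
        obs = sample_pseudo_absences(mask, 25, seed=2)
        row, col = mask.index_of(obs.x, obs.y)
        assert len(set(zip(row, col))) == 25

    def test_deterministic(self):
        mask = Grid(values=np.ones((20, 20)), pixel_size=30.0)
        a = sample_pseudo_absences(mask, 50, seed=3)
        b = sample_pseudo_absences(mask, 50, seed=3)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_distinct_pixels(self):
        mask = Grid(values=np.ones((20, 20)), pixel_size=30.0)
        obs = sample_pseudo_absences(mask, 300, seed=4)
        row, col = mask.index_of(obs.x, obs.y)
        assert len(set(zip(row, col))) == 300

    def test_too_many_requested(self):
        mask = Grid(values=np.ones((4, 4)), pixel_size=30.0)
        with pytest.raises(ValueError):
            sample_pseudo_absences(mask, 17, seed=0)

    def test_respects_mask_zeros(self):
        values = np.ones((10, 10))
        values[:, :5] = 0
        mask = Grid(values=values, pixel_size=30.0)
        obs = sample_pseudo_absences(mask, 30, seed=5)
        row, col = mask.index_of(obs.x, obs.y)
        assert np.all(col >= 5)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 0], [0.9, 0.1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            n = 50
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            scores = np.round(rng.uniform(0, 1, n), 1)  # force some ties
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert roc_auc(labels, scores) == pytest.approx(oracle)

    def test_complement_under_score_negation(self):
        rng = np.random.default_rng(21)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        scores = rng.uniform(0, 1, 40)  # continuous -> tie-free
        assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.4])


class TestFitOccurrence:
    def test_strong_signal_high_oob_roc(self):
        for seed in range(5):
            samples = make_samples(np.random.default_rng(seed), n=500)
            model = fit_occurrence(samples, n_trees=300, seed=seed)
            assert model.oob_roc_auc_ >= 0.95

    def test_permuted_labels_near_chance(self):
        for seed in range(5):
            samples = make_samples(np.random.default_rng(seed), n=500, signal="null")
            model = fit_occurrence(samples, n_trees=300, seed=seed)
            assert 0.40 <= model.oob_roc_auc_ <= 0.60

    def test_single_class_raises(self):
        samples = make_samples(np.random.default_rng(0), n=100)
        samples["presence"] = 1
        with pytest.raises(ValueError):
            fit_occurrence(samples, n_trees=50, seed=0)

    def test_oob_roc_internally_consistent(self):
        samples = make_samples(np.random.default_rng(3), n=300)
        model = fit_occurrence(samples, n_trees=200, seed=3)
        assert model.oob_roc_auc_ == pytest.approx(
            roc_auc(samples["presence"].to_numpy(), model.oob_scores_)
        )

    def test_sklearn_params_roundtrip(self):
        model = OccurrenceModel(n_trees=123, balanced=False, seed=9)
        params = model.get_params()
        clone = OccurrenceModel(**params)
        assert clone.get_params() == params


class TestPredictRio:
    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(7)
        samples = make_samples(rng, n=400)
        model = fit_occurrence(samples, n_trees=150, seed=7)
        layers = {}
        for i, name in enumerate(model.feature_names_):
            vals = rng.uniform(0, 1, (12, 14))
            nodata = np.zeros((12, 14), dtype=bool)
            nodata[0, i] = True
            layers[name] = Grid(values=vals, pixel_size=30.0, nodata=nodata)
        return model, PredictorStack(layers)

    def test_values_in_unit_interval(self, fitted):
        model, stack = fitted
        rio = predict_rio(model, stack)
        assert np.nanmin(rio.valid_values()) >= 0.0
        assert np.nanmax(rio.valid_values()) <= 1.0

    def test_nodata_propagates(self, fitted):
        model, stack = fitted
        rio = predict_rio(model, stack)
        assert np.array_equal(rio.nodata, stack.combined_nodata())

    def test_matches_extract_then_predict_oracle(self, fitted):
        model, stack = fitted
        rio = predict_rio(model, stack)
        X, valid = stack.as_matrix(model.feature_names_)
        direct = model.vote_fraction(X)
        assert np.allclose(rio.values[valid], direct)

    def test_missing_layer_raises(self, fitted):
        model, stack = fitted
        partial = PredictorStack({n: stack[n] for n in model.feature_names_[:-1]})
        with pytest.raises(ValueError):
            predict_rio(model, partial)


class TestVariableImportance:
    def test_driver_ranks_first_across_seeds(self):
        hits = 0
        for seed in range(20):
            samples = make_samples(np.random.default_rng(seed), n=300)
            model = fit_occurrence(samples, n_trees=150, seed=seed)
            ranking = variable_importance(model)
            if ranking[0][0] == "x0":
                hits += 1
        assert hits >= 18

    def test_null_importances_unstable(self):
        tops = set()
        for seed in range(8):
            samples = make_samples(np.random.default_rng(100 + seed), n=300,
                                   signal="null")
            model = fit_occurrence(samples, n_trees=100, seed=seed)
            tops.add(variable_importance(model)[0][0])
        assert len(tops) >= 2  # no predictor dominates pure noise

    def test_all_predictors_listed_descending(self):
        samples = make_samples(np.random.default_rng(1), n=200)
        model = fit_occurrence(samples, n_trees=100, seed=1)
        ranking = variable_importance(model)
        assert len(ranking) == 3
        scores = [s for _, s in ranking]
        assert scores == sorted(scores, reverse=True)
        assert all(s >= 0 for s in scores)


class TestPartialDependence:
    def test_recovers_step_location(self):
        rng = np.random.default_rng(30)
        samples = make_samples(rng, n=400)
        model = fit_occurrence(samples, n_trees=200, seed=30)
        curve = partial_dependence(model, samples, "x0", n_grid=100)
        values = np.array([v for v, _ in curve])
        resp = np.array([r for _, r in curve])
        jump_at = values[np.argmax(np.diff(resp))]
        grid_cell = values[1] - values[0]
        assert abs(jump_at - 0.5) <= 2 * grid_cell

    def test_variable_outside_selected_set_is_flat(self):
        # a variable the fitted model does not use yields a flat curve
        rng = np.random.default_rng(31)
        df = pd.DataFrame({"x0": rng.uniform(0, 1, 300),
                           "x1": rng.uniform(0, 1, 300)})
        df["count"] = np.round(40 * df["x0"]).astype(int)
        from priorimap.abundance import fit_abundance

        model = fit_abundance(df, ["x0"], n_trees=150, seed=31)
        curve = partial_dependence(model, df, "x1", n_grid=50)
        resp = np.array([r for _, r in curve])
        assert resp.max() - resp.min() < 0.01 * df["count"].max()

    def test_matches_substitution_average_oracle(self):
        rng = np.random.default_rng(32)
        samples = make_samples(rng, n=120)
        model = fit_occurrence(samples, n_trees=80, seed=32)
        curve = partial_dependence(model, samples, "x0", n_grid=7)
        X = samples[model.feature_names_].to_numpy()
        col = model.feature_names_.index("x0")
        for v, r in curve:
            Xm = X.copy()
            Xm[:, col] = v
            assert r == pytest.approx(model.vote_fraction(Xm).mean())

    def test_unknown_variable_raises(self):
        samples = make_samples(np.random.default_rng(1), n=100)
        model = fit_occurrence(samples, n_trees=50, seed=1)
        with pytest.raises(ValueError):
            partial_dependence(model, samples, "zzz")
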