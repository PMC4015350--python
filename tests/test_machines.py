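"""Probability machines and logistic comparators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riskmachines as rm


class TestFitPM:
    def test_constant_outcome_predicts_the_constant(self, tiny_data):
        data = rm.BinaryDataset(
            y=np.ones(200, dtype=int), X=tiny_data.X, feature_names=tiny_data.feature_names
        )
        pm = rm.fit_pm(data, rm.PMConfig(seed=1))
        assert np.all(pm.predict(data.to_frame().drop(columns="y")) == 1.0)

    def test_single_feature_predictions_match_stratum_means(self):
        """On one binary feature the PM converges to within-stratum outcome means."""
        rng = np.random.default_rng(11)
        x = (rng.random(10_000) < 0.5).astype(int)
        y = (rng.random(10_000) < np.where(x == 1, 0.8, 0.2)).astype(int)
        data = rm.BinaryDataset(y=y, X=x[:, None], feature_names=("X1",))
        pm = rm.fit_pm(data, rm.PMConfig(seed=2))
        pred = pm.predict(np.array([[0.0], [1.0]]))
        for level, expect in ((0, y[x == 0].mean()), (1, y[x == 1].mean())):
            assert pred[level] == pytest.approx(expect, abs=0.02)

    @staticmethod
    def _stratum_weighted_error(spec, pm, seed):
        """Frequency-weighted mean |stratum-mean prediction - truth| on an
        independent evaluation draw from the same law."""
        eval_data = rm.simulate(spec, 4000, seed=seed)
        pred = pm.predict(eval_data.to_frame().drop(columns="y"))
        truth = np.asarray(rm.true_probability(spec, eval_data.X))
        err, weight = 0.0, 0
        from itertools import product

        for combo in product((0, 1), repeat=3):
            mask = np.all(eval_data.X[:, :3] == combo, axis=1)
            err += abs(pred[mask].mean() - truth[mask].mean()) * mask.sum()
            weight += mask.sum()
        return err / weight

    def test_stratum_means_track_true_probabilities_on_average(self, model1_data):
        spec = rm.builtin_model("model1")
        pm = rm.fit_pm(model1_data, rm.PMConfig(seed=3))
        assert self._stratum_weighted_error(spec, pm, seed=22) < 0.05

    def test_interaction_model_probabilities_recovered(self):
        """A single RFPM tracks interaction-model probabilities without
        any interaction being specified."""
        spec = rm.builtin_model("model2")
        data = rm.simulate(spec, 1000, seed=21)
        pm = rm.fit_pm(data, rm.PMConfig(seed=4))
        assert self._stratum_weighted_error(spec, pm, seed=23) < 0.05

    def test_excluded_features_never_enter_the_design(self, tiny_data):
        pm = rm.fit_pm(tiny_data, rm.PMConfig(seed=5), exclude_features={"X1"})
        assert pm.feature_names == ("X2",)
        with pytest.raises(ValueError):
            rm.fit_pm(tiny_data, exclude_features={"X9"})

    def test_identical_config_gives_identical_predictions(self, tiny_data):
        X = tiny_data.to_frame().drop(columns="y")
        p1 = rm.fit_pm(tiny_data, rm.PMConfig(seed=6)).predict(X)
        p2 = rm.fit_pm(tiny_data, rm.PMConfig(seed=6)).predict(X)
        assert np.array_equal(p1, p2)

    def test_nodesize_resolution(self):
        cfg = rm.PMConfig(nodesize_fraction=0.05)
        assert cfg.resolved_nodesize(1000) == 50
        assert cfg.resolved_nodesize(90) == 5
        assert cfg.resolved_nodesize(3) == 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            rm.PMConfig(n_trees=0)
        with pytest.raises(ValueError):
            rm.PMConfig(nodesize_fraction=1.5)
        with pytest.raises(ValueError):
            rm.PMConfig(mtry_policy="half")


class TestPredictPM:
    def test_column_mismatch_is_named(self, tiny_data):
        pm = rm.fit_pm(tiny_data, rm.PMConfig(seed=7))
        df = tiny_data.to_frame().drop(columns=["y", "X2"])
        with pytest.raises(ValueError, match="X2"):
            pm.predict(df)

    def test_row_order_invariance(self, tiny_data):
        pm = rm.fit_pm(tiny_data, rm.PMConfig(seed=8))
        X = tiny_data.to_frame().drop(columns="y")
        perm = np.random.default_rng(0).permutation(len(X))
        assert np.array_equal(pm.predict(X)[perm], pm.predict(X.iloc[perm]))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_predictions_always_probabilities(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(40, 120), rng.integers(1, 5)
        X = (rng.random((n, p)) < rng.random(p)).astype(int)
        y = (rng.random(n) < 0.5).astype(int)
        names = tuple(f"X{i+1}" for i in range(p))
        data = rm.BinaryDataset(y=y, X=X, feature_names=names)
        pm = rm.fit_pm(data, rm.PMConfig(n_trees=10, seed=int(seed)))
        pred = pm.predict(X.astype(float))
        assert np.all((pred >= 0) & (pred <= 1))


class TestLogistic:
    def test_lr1_recovers_its_own_generating_model(self):
        data = rm.simulate(rm.builtin_model("model1"), 20_000, seed=31)
        fit = rm.fit_logistic(data, "LR1")
        assert fit.converged
        assert fit.odds_ratio("X3") == pytest.approx(2.0, rel=0.10)

    def test_lr2_recovers_a_strong_interaction(self):
        data = rm.simulate(rm.builtin_model("model2"), 20_000, seed=32)
        fit = rm.fit_logistic(data, "LR2")
        assert fit.odds_ratio("X2:X3") == pytest.approx(5.0, rel=0.15)

    def test_null_data_gives_null_coefficients(self):
        spec = rm.LogisticModelSpec(n_features=4, baseline_prob=0.4)
        data = rm.simulate(spec, 20_000, seed=33)
        fit = rm.fit_logistic(data, "LR1")
        assert np.all(np.abs(fit.params.drop("const")) < 0.1)

    def test_lr2_design_has_all_pairwise_terms(self, model1_data):
        fit = rm.fit_logistic(model1_data, "LR2")
        p = model1_data.p
        assert len(fit.term_names) == 1 + p + p * (p - 1) // 2

    def test_predict_matches_fitted_probabilities(self, model1_data):
        import statsmodels.api as sm

        fit = rm.fit_logistic(model1_data, "LR1")
        X = model1_data.to_frame().drop(columns="y")
        D = sm.add_constant(X.to_numpy(dtype=float))
        direct = sm.GLM(
            model1_data.y.astype(float), D, family=sm.families.Binomial()
        ).fit()
        assert np.allclose(fit.predict(X), direct.predict(D), atol=1e-8)

    def test_trivial_linear_predictors(self, tiny_data):
        import pandas as pd
        from scipy.special import logit as lgt

        fit = rm.FittedLogit(
            design="LR1",
            feature_names=("X1", "X2"),
            params=pd.Series([0.0, 0.0, 0.0], index=["const", "X1", "X2"]),
        )
        X = tiny_data.to_frame().drop(columns="y")
        assert np.allclose(fit.predict(X), 0.5)
        fit.params["const"] = lgt(0.3)
        assert np.allclose(fit.predict(X), 0.3)

    def test_underdetermined_design_rejected(self):
        rng = np.random.default_rng(0)
        data = rm.BinaryDataset(
            y=(rng.random(8) < 0.5).astype(int),
            X=(rng.random((8, 10)) < 0.5).astype(int),
            feature_names=tuple(f"X{i+1}" for i in range(10)),
        )
        with pytest.raises(ValueError, match="parameters"):
            rm.fit_logistic(data, "LR1")

    def test_separation_is_flagged_not_fatal(self):
        x = np.repeat([0, 1], 30)
        data = rm.BinaryDataset(y=x, X=x[:, None], feature_names=("X1",))
        fit = rm.fit_logistic(data, "LR1")
        assert not fit.converged


class TestClip:
    @given(st.floats(0, 1), st.floats(1e-6, 0.4))
    def test_clip_is_an_order_preserving_clamp(self, p, eps):
        out = float(rm.clip_probability(p, eps))
        assert eps <= out <= 1 - eps
        if eps < p < 1 - eps:
            assert out == p

    def test_clip_rejects_bad_eps(self):
        with pytest.raises(ValueError):
            rm.clip_probability(0.5, 0.7)


def test_pm_round_trips_through_disk(tiny_data, tmp_path):
    pm = rm.fit_pm(tiny_data, rm.PMConfig(seed=9))
    rm.save_pm(pm, tmp_path / "pm.joblib")
    back = rm.load_pm(tmp_path / "pm.joblib")
    X = tiny_data.to_frame().drop(columns="y")
    assert np.array_equal(pm.predict(X), back.predict(X))
    assert (tmp_path / "pm.joblib.json").exists()
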