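"""Cross-validated scoring, model comparison statistics, tuning, populations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from anppgrid import cv as cvs
from anppgrid import harness


def _linear_data(n=60, p=4, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.arange(1, p + 1, dtype=float)
    y = 100 + X @ beta + noise * rng.normal(size=n)
    return X, y


class TestCrossValidate:
    def test_linear_learner_recovers_linear_response(self):
        X, y = _linear_data()
        folds = cvs.random_kfold(len(y), 5, seed=0)
        s = harness.cross_validate(harness.LearnerSpec("linear"), X, y, folds)
        assert s.r2 >= 0.999
        assert s.rmse == pytest.approx(0.0, abs=1e-6)

    def test_training_mean_prediction_scores_nonpositive_r2(self):
        # a constant predictor column forces the linear learner to predict the
        # training-fold mean, whose pooled out-of-fold R2 cannot exceed 0
        rng = np.random.default_rng(1)
        X = np.ones((40, 1))
        y = rng.normal(size=40)
        s = harness.cross_validate(harness.LearnerSpec("linear"), X, y, cvs.random_kfold(40, 5, 0))
        assert s.r2 <= 0

    def test_metrics_match_hand_formulas(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        pred = np.array([1.5, 1.5, 3.5, 3.5, 5.5, 5.5])
        s = harness.score_predictions(obs, pred)
        resid = obs - pred
        assert s.rmse == pytest.approx(np.sqrt(np.mean(resid**2)))
        assert s.mae == pytest.approx(np.mean(np.abs(resid)))
        ss_res = np.sum(resid**2)
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        assert s.r2 == pytest.approx(1 - ss_res / ss_tot)
        assert s.rmse >= s.mae >= 0

    def test_mismatched_folds_error(self):
        X, y = _linear_data(30)
        with pytest.raises(ValueError):
            harness.cross_validate(harness.LearnerSpec("linear"), X, y, cvs.random_kfold(29, 5, 0))


class TestCompareModels:
    def test_repeat_count(self):
        X, y = _linear_data(50, noise=1.0)
        out = harness.compare_models(
            {"lm": harness.LearnerSpec("linear")}, ["random", "env_stratified"],
            X, y, strat_features=X, k=5, repeats=10,
        )
        assert len(out) == 20
        assert set(out["strategy"]) == {"random", "env_stratified"}
        assert out.groupby("strategy").size().eq(10).all()

    def test_duplicated_learner_identical_scores(self):
        X, y = _linear_data(50, noise=1.0)
        out = harness.compare_models(
            {"a": harness.LearnerSpec("linear"), "b": harness.LearnerSpec("linear")},
            ["random"], X, y, k=5, repeats=3,
        )
        a = out[out["learner"] == "a"].sort_values("repeat")["r2"].values
        b = out[out["learner"] == "b"].sort_values("repeat")["r2"].values
        assert np.array_equal(a, b)

    def test_single_cell_design_rejected(self):
        X, y = _linear_data(30)
        with pytest.raises(ValueError):
            harness.compare_models({"lm": harness.LearnerSpec("linear")}, ["random"], X, y)


class TestCompareStats:
    @staticmethod
    def _scores(shift_c=0.0, seed=0, repeats=10):
        rng = np.random.default_rng(seed)
        rows = []
        for rep in range(repeats):
            for g in ("a", "b", "c"):
                rows.append(
                    {"learner": g, "strategy": "random", "repeat": rep,
                     "r2": rng.normal(0.6, 0.01) + (shift_c if g == "c" else 0.0)}
                )
        return pd.DataFrame(rows)

    def test_null_behaviour(self):
        # same-distribution groups: ANOVA should rarely reject
        ps = [harness.compare_stats(self._scores(seed=s)).anova_p for s in range(20)]
        assert np.mean(np.array(ps) > 0.05) >= 0.9

    def test_shifted_group_detected(self):
        rep = harness.compare_stats(self._scores(shift_c=0.1))
        assert rep.anova_p < 0.001
        sig = rep.tukey[rep.tukey["reject"] == True]  # noqa: E712
        assert {"c"} <= set(sig["group1"]).union(sig["group2"])

    def test_identical_groups_zero_difference(self):
        df = self._scores()
        df.loc[df["learner"] == "b", "r2"] = df.loc[df["learner"] == "a", "r2"].values
        rep = harness.compare_stats(df)
        ab = rep.tukey[(rep.tukey["group1"] == "a") & (rep.tukey["group2"] == "b")]
        assert float(ab["meandiff"].iloc[0]) == pytest.approx(0.0, abs=1e-12)

    def test_unbalanced_design_rejected(self):
        df = self._scores().iloc[:-1]
        with pytest.raises(ValueError):
            harness.compare_stats(df)


class TestGridSearch:
    def test_single_combination_selected(self):
        X, y = _linear_data(60, noise=5.0)
        table, sel = harness.grid_search(
            X, y, X, grid={"ntree": [50], "mtry": [2]}, repeats=2, k=5, n_classes=3
        )
        assert sel == (50, 2)
        assert len(table) == 2

    def test_table_covers_grid_times_repeats(self):
        X, y = _linear_data(60, noise=5.0)
        table, _ = harness.grid_search(
            X, y, X, grid={"ntree": [20, 40], "mtry": [2, 3]}, repeats=2, k=5, n_classes=3
        )
        assert len(table) == 8
        assert "mean_r2" in table.columns

    def test_tie_breaks_prefer_smaller_ntree_then_mtry(self):
        means = pd.DataFrame(
            {"ntree": [400, 200, 200], "mtry": [2, 6, 4], "mean_r2": [0.5, 0.5, 0.5]}
        )
        assert harness.select_best_combination(means) == (200, 4)

    def test_infeasible_mtry_skipped(self, caplog):
        X, y = _linear_data(60, p=3, noise=5.0)
        table, sel = harness.grid_search(
            X, y, X, grid={"ntree": [20], "mtry": [2, 10]}, repeats=1, k=5, n_classes=3
        )
        assert set(table["mtry"]) == {2}
        assert sel == (20, 2)


class TestPopulationAndEnsemble:
    def test_population_best_is_argmax(self):
        X, y = _linear_data(60, noise=10.0)
        pop = harness.train_population(
            X, y, [f"x{i}" for i in range(X.shape[1])],
            harness.LearnerSpec("random_forest", {"ntree": 30, "mtry": 2}),
            X, n_models=5, k=5, n_classes=3,
        )
        assert len(pop.models) == 5
        r2s = pop.r2_values()
        assert pop.best.score.r2 == r2s.max()
        single = harness.train_population(
            X, y, [f"x{i}" for i in range(X.shape[1])],
            harness.LearnerSpec("random_forest", {"ntree": 10, "mtry": 2}),
            X, n_models=1, k=5, n_classes=3,
        )
        assert single.best_index == 0

    def test_population_reproducible(self):
        X, y = _linear_data(50, noise=10.0)
        args = (X, y, ["a", "b", "c", "d"],
                harness.LearnerSpec("random_forest", {"ntree": 20, "mtry": 2}), X)
        p1 = harness.train_population(*args, n_models=3, k=5, n_classes=3, base_seed=1)
        p2 = harness.train_population(*args, n_models=3, k=5, n_classes=3, base_seed=1)
        assert np.array_equal(p1.r2_values(), p2.r2_values())
        assert p1.best_index == p2.best_index

    def test_ensemble_average(self):
        class Const:
            def __init__(self, c):
                self.c = c

            def predict(self, X):
                return np.full(len(X), self.c)

        m1 = harness.FittedModel(Const(100.0), ("a",), harness.LearnerSpec("linear"))
        m2 = harness.FittedModel(Const(200.0), ("a",), harness.LearnerSpec("linear"))
        X = np.zeros((3, 1))
        assert np.allclose(harness.ensemble_predict([m1, m2], X), 150.0)
        assert np.allclose(harness.ensemble_predict([m1], X), 100.0)
        m3 = harness.FittedModel(Const(1.0), ("a", "b"), harness.LearnerSpec("linear"))
        with pytest.raises(ValueError, match="schema"):
            harness.ensemble_predict([m1, m3], X)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=5), st.integers(0, 10))
    def test_ensemble_mean_within_member_range(self, consts, seed):
        class Const:
            def __init__(self, c):
                self.c = c

            def predict(self, X):
                return np.full(len(X), self.c)

        models = [
            harness.FittedModel(Const(c), ("a",), harness.LearnerSpec("linear")) for c in consts
        ]
        out = harness.ensemble_predict(models, np.zeros((4, 1)))
        assert (out >= min(consts) - 1e-9).all() and (out <= max(consts) + 1e-9).all()
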