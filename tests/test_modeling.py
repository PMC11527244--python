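"""Logistic models, bootstrap-stepwise selection, CART and reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from hrvarousal.config import NEGATIVE_LABEL, POSITIVE_LABEL, AnalysisConfig
from hrvarousal.modeling import (
    ArousalLogit,
    ArousalTree,
    ClassificationReport,
    auroc,
    best_split,
    bootstrap_stepwise_select,
    classify,
    fit_cart,
    fit_logistic,
    predict_tree,
    rcs_basis,
    spline_loglinearity_test,
    summarize,
    youden_threshold,
)
from hrvarousal.simulate import simulate_feature_table


def labels_from(y: np.ndarray) -> np.ndarray:
    return np.where(y, POSITIVE_LABEL, NEGATIVE_LABEL)


class TestSummarize:
    def test_median_iqr(self):
        df = pd.DataFrame({"v": [1.0, 2, 3, 4, 5]})
        out = summarize(df, ["v"], mode="median")
        assert out.iloc[0]["display"] == "3 [2–4]"

    def test_constant_sd_zero(self):
        df = pd.DataFrame({"v": [5.0] * 10})
        out = summarize(df, ["v"], mode="mean")
        assert out.iloc[0]["display"] == "5 ± 0"

    def test_categorical_counts(self):
        df = pd.DataFrame({"sex": ["m"] * 13 + ["f"] * 21})
        out = summarize(df, ["sex"])
        disp = dict(zip(out["variable"], out["display"]))
        assert disp["sex=m"] == "13/34 (38.24)"


class TestSplineTest:
    def test_lr_statistic_nonnegative(self, rng):
        for s in range(5):
            sim = simulate_feature_table(300, {"X": 0.4}, seed=s)
            res = spline_loglinearity_test(sim.table, "X")
            assert res["lr_statistic"] >= 0.0

    def test_power_against_log_dependence(self):
        # logit linear in log(x) with x spanning decades -> spline test rejects
        sim = simulate_feature_table(
            2000, {"X": 1.2}, seed=3, lognormal=("X",), scales={"X": (0.0, 1.6)}
        )
        res = spline_loglinearity_test(sim.table, "X")
        assert res["p"] < 0.05 and res["transform"] == "log"

    def test_type_i_error_controlled(self):
        rejections = 0
        n_sims = 40
        for s in range(n_sims):
            sim = simulate_feature_table(800, {"X": 0.5}, seed=100 + s)
            rejections += spline_loglinearity_test(sim.table, "X")["p"] < 0.05
        assert rejections / n_sims < 0.2

    def test_rcs_basis_shape_and_linearity_tail(self):
        knots = np.array([0.0, 1.0, 2.0, 3.0])
        x = np.linspace(-2, 6, 200)
        B = rcs_basis(x, knots)
        assert B.shape == (200, 3)
        # restricted: linear beyond the outer knots
        tail = x > 4.0
        for j in range(1, 3):
            d2 = np.diff(B[tail, j], 2)
            assert np.allclose(d2, 0.0, atol=1e-8)

    def test_needs_rows(self):
        sim = simulate_feature_table(20, {"X": 0.0}, seed=0)
        with pytest.raises(ValueError, match="30"):
            spline_loglinearity_test(sim.table, "X")


class TestFitLogistic:
    def test_null_model_intercept(self):
        y = np.array([True] * 30 + [False] * 70)
        df = pd.DataFrame({"class": labels_from(y)})
        m = fit_logistic(df, [])
        assert m.params["const"] == pytest.approx(np.log(0.3 / 0.7), abs=1e-6)

    def test_null_effect_or_near_one(self):
        sim = simulate_feature_table(2000, {"X": 0.0}, seed=1)
        m = fit_logistic(sim.table, ["X"])
        assert 0.9 < np.exp(m.params["X"]) < 1.1

    def test_coefficient_recovery(self):
        sim = simulate_feature_table(2000, {"X": 0.05}, seed=2, scales={"X": (0.0, 20.0)})
        m = fit_logistic(sim.table, ["X"])
        # per-unit OR on the observed scale: exp(0.05/20)
        lo, hi = m.conf_int.loc["X", 0], m.conf_int.loc["X", 1]
        assert lo < 0.05 / 20.0 < hi

    def test_perfect_separation_error(self):
        x = np.arange(40, dtype=float)
        df = pd.DataFrame({"x": x, "class": labels_from(x >= 20)})
        with pytest.raises(ValueError, match="separation"):
            fit_logistic(df, ["x"])

    def test_log_transform_design(self):
        sim = simulate_feature_table(200, {"X": 0.5}, seed=4, lognormal=("X",))
        m = fit_logistic(sim.table, ["X"], {"X": "log"})
        assert "log(X)" in m.params.index
        p = m.predict(sim.table)
        assert np.all((p > 0) & (p < 1))

    def test_log_transform_requires_positive(self):
        df = pd.DataFrame({"x": [-1.0, 2.0] * 20,
                           "class": labels_from(np.arange(40) % 2 == 0)})
        with pytest.raises(ValueError, match="positive"):
            fit_logistic(df, ["x"], {"x": "log"})

    def test_odds_ratio_identities(self):
        sim = simulate_feature_table(500, {"X": 0.8}, seed=5)
        m = fit_logistic(sim.table, ["X"])
        orr = m.odds_ratios
        assert orr.loc["X", "OR"] == pytest.approx(np.exp(m.params["X"]))
        assert orr.loc["X", "ci_low"] < orr.loc["X", "OR"] < orr.loc["X", "ci_high"]
        assert "const" not in orr.index


class TestAUROC:
    def test_perfect(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([True, True, False, False])
        auc, (lo, hi) = auroc(scores, y)
        assert auc == 1.0 and 0 <= lo <= hi <= 1

    def test_all_equal(self):
        auc, _ = auroc(np.ones(10), np.arange(10) % 2 == 0)
        assert auc == 0.5

    def test_hand_example(self):
        auc, _ = auroc(np.array([0.8, 0.4, 0.6, 0.2]),
                       np.array([True, True, False, False]))
        assert auc == pytest.approx(0.75)

    def test_string_labels(self):
        scores = np.array([0.8, 0.4, 0.6, 0.2])
        labels = np.array([POSITIVE_LABEL, POSITIVE_LABEL,
                           NEGATIVE_LABEL, NEGATIVE_LABEL])
        assert auroc(scores, labels)[0] == pytest.approx(0.75)
        assert auroc(scores, pd.Series(labels).to_numpy())[0] == pytest.approx(0.75)

    def test_one_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc(np.array([0.1, 0.2]), np.array([True, True]))

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            n = int(rng.integers(10, 60))
            scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            auc, _ = auroc(scores, y)
            assert auc == pytest.approx(roc_auc_score(y, scores))

    def test_delong_ci_brackets_point(self, rng):
        scores = rng.random(80)
        y = rng.random(80) < 0.5
        auc, (lo, hi) = auroc(scores, y)
        assert 0 <= lo <= auc <= hi <= 1


class TestClassificationReport:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(hst.integers(1, 500), hst.integers(1, 500),
           hst.integers(1, 500), hst.integers(1, 500))
    def test_metric_identities(self, tp, fp, tn, fn):
        r = ClassificationReport(tp=tp, fp=fp, tn=tn, fn=fn)
        assert r.sensitivity == tp / (tp + fn)
        assert r.specificity == tn / (tn + fp)
        assert r.ppv == tp / (tp + fp)
        assert r.npv == tn / (tn + fn)

    def test_from_counts_validates_partition(self):
        by_tp = pd.DataFrame({"timepoint_min": [0, 2], "n_pos": [5, 5],
                              "n_neg": [5, 5], "fn": [1, 1], "fp": [2, 0]})
        with pytest.raises(ValueError, match="sum"):
            ClassificationReport.from_counts(9, 3, 7, 1, by_timepoint=by_tp)

    def test_threshold_zero_all_positive(self):
        sim = simulate_feature_table(300, {"X": 1.0}, seed=6)
        m = fit_logistic(sim.table, ["X"])
        rep = classify(m, sim.table, threshold=1e-12)
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0

    def test_threshold_validation(self):
        sim = simulate_feature_table(100, {"X": 1.0}, seed=6)
        m = fit_logistic(sim.table, ["X"])
        with pytest.raises(ValueError, match="threshold"):
            classify(m, sim.table, threshold=1.5)

    def test_by_timepoint_partition(self, study_table):
        m = fit_logistic(study_table, ["SDNN"], {"SDNN": "log"})
        rep = classify(m, study_table, 0.39)
        assert rep.by_timepoint["fn"].sum() == rep.fn
        assert rep.by_timepoint["fp"].sum() == rep.fp
        assert rep.by_timepoint["n_pos"].sum() == rep.tp + rep.fn
        assert rep.by_timepoint["n_neg"].sum() == rep.tn + rep.fp

    def test_youden(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        labels = labels_from(np.array([True, True, False, False]))
        assert youden_threshold(scores, labels) == pytest.approx(0.8)


class TestBootstrapStepwise:
    def test_single_strong_variable_b1(self):
        sim = simulate_feature_table(400, {"X": 1.5}, seed=7)
        trace = bootstrap_stepwise_select(sim.table, ["X"], B=1, seed=0)
        assert trace.frequencies["X"] == 1.0
        assert trace.retained == ["X"]

    def test_order_invariance(self):
        sim = simulate_feature_table(250, {"A": 1.0, "B": 0.0, "C": 0.3}, seed=8)
        t1 = bootstrap_stepwise_select(sim.table, ["A", "B", "C"], B=25, seed=3)
        t2 = bootstrap_stepwise_select(sim.table, ["C", "A", "B"], B=25, seed=3)
        assert t1.frequencies.equals(t2.frequencies)

    def test_all_noise_mostly_empty(self):
        empty = 0
        for s in range(10):
            sim = simulate_feature_table(200, {"A": 0.0, "B": 0.0}, seed=50 + s)
            trace = bootstrap_stepwise_select(sim.table, ["A", "B"], B=20, seed=s)
            empty += not trace.retained
        assert empty >= 9

    def test_validation(self):
        sim = simulate_feature_table(100, {"X": 0.5}, seed=9)
        with pytest.raises(ValueError):
            bootstrap_stepwise_select(sim.table, [], B=10)
        with pytest.raises(ValueError):
            bootstrap_stepwise_select(sim.table, ["X"], B=0)


def exhaustive_root_split(table, variables, y):
    """Independent oracle: naive double loop over variables and midpoints."""
    n = len(y)

    def gini(pos, tot):
        if tot == 0:
            return 0.0
        p = pos / tot
        return 2 * p * (1 - p)

    parent = gini(y.sum(), n)
    best = None
    for v in variables:
        x = table[v].to_numpy(float)
        for t in np.unique(x)[:-1]:
            uniq = np.unique(x)
            thr = (t + uniq[uniq > t][0]) / 2.0
            left = x < thr
            gain = parent - (
                left.sum() / n * gini(y[left].sum(), left.sum())
                + (~left).sum() / n * gini(y[~left].sum(), (~left).sum())
            )
            if best is None or gain > best[2] + 1e-12:
                best = (v, thr, gain)
    return best


class TestCART:
    def test_separable_1d(self):
        x = np.concatenate([np.arange(0.0, 5.0, 0.25), np.arange(5.0, 10.0, 0.25)])
        df = pd.DataFrame({"x": x, "class": labels_from(x >= 5.0)})
        tree = fit_cart(df, ["x"], min_split=2, min_leaf=1)
        assert tree.root.variable == "x"
        assert tree.root.threshold == pytest.approx(4.875)
        rep = predict_tree(tree, df)
        assert rep.fn == 0 and rep.fp == 0

    def test_pure_input_single_leaf(self):
        df = pd.DataFrame({"x": np.arange(30.0),
                           "class": [POSITIVE_LABEL] * 30})
        tree = fit_cart(df, ["x"])
        assert tree.root.is_leaf and tree.root.predicted == POSITIVE_LABEL

    def test_root_matches_exhaustive_oracle(self, rng):
        for s in range(5):
            sim = simulate_feature_table(150, {"A": 0.8, "B": 0.3, "C": 0.0},
                                         seed=20 + s)
            y = (sim.table["class"] == POSITIVE_LABEL).to_numpy()
            ours = best_split(sim.table, ["A", "B", "C"], y.astype(float), min_leaf=1)
            oracle = exhaustive_root_split(sim.table, ["A", "B", "C"], y)
            assert ours[0] == oracle[0]
            assert ours[1] == pytest.approx(oracle[1])
            assert ours[2] == pytest.approx(oracle[2])

    def test_root_matches_sklearn(self):
        from sklearn.tree import DecisionTreeClassifier

        sim = simulate_feature_table(200, {"A": 1.0, "B": 0.2}, seed=31)
        y = (sim.table["class"] == POSITIVE_LABEL).to_numpy()
        ours = best_split(sim.table, ["A", "B"], y.astype(float), min_leaf=1)
        sk = DecisionTreeClassifier(max_depth=1, random_state=0).fit(
            sim.table[["A", "B"]], y
        )
        assert ["A", "B"][sk.tree_.feature[0]] == ours[0]
        assert sk.tree_.threshold[0] == pytest.approx(ours[1], abs=1e-6)

    def test_tie_break_by_variable_order(self):
        # two identical predictors: the first in declared order wins
        x = np.array([0.0] * 10 + [1.0] * 10)
        df = pd.DataFrame({"b": x, "a": x, "class": labels_from(x > 0.5)})
        tree = fit_cart(df, ["b", "a"], min_split=2, min_leaf=1)
        assert tree.root.variable == "b"
        tree2 = fit_cart(df, ["a", "b"], min_split=2, min_leaf=1)
        assert tree2.root.variable == "a"

    def test_child_counts_sum(self, study_table):
        tree = fit_cart(study_table, ["SDNN", "RMSSD", "LF", "HR", "ANI"])

        def check(node):
            if node.is_leaf:
                return
            assert node.left.n_pos + node.right.n_pos == node.n_pos
            assert node.left.n_neg + node.right.n_neg == node.n_neg
            check(node.left)
            check(node.right)

        check(tree.root)

    def test_accuracy_non_decreasing_as_min_leaf_shrinks(self):
        sim = simulate_feature_table(300, {"A": 0.8, "B": 0.4}, seed=33)
        accs = []
        for leaf in (40, 20, 7, 2):
            tree = fit_cart(sim.table, ["A", "B"], min_split=4, min_leaf=leaf,
                            min_improvement=0.0)
            rep = predict_tree(tree, sim.table)
            accs.append((rep.tp + rep.tn) / len(sim.table))
        assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:]))

    def test_missing_split_value_error(self):
        x = np.array([0.0] * 15 + [1.0] * 15)
        df = pd.DataFrame({"x": x, "class": labels_from(x > 0.5)})
        tree = fit_cart(df, ["x"], min_split=2, min_leaf=1)
        bad = pd.DataFrame({"x": [np.nan], "class": [POSITIVE_LABEL],
                            "timepoint_min": [0]})
        with pytest.raises(ValueError, match="missing"):
            tree.predict_row(bad.iloc[0])

    def test_empty_table_error(self):
        df = pd.DataFrame({"x": [], "class": []})
        with pytest.raises(ValueError, match="empty"):
            fit_cart(df, ["x"])


@pytest.fixture(scope="module")
def fitted(study_table):
    cfg = AnalysisConfig(bootstrap_replicates=40)
    model = ArousalLogit(study_table, ["SDNN", "RMSSD", "LF", "HR", "ANI"], cfg)
    return model.fit(seed=0)


class TestModelClasses:
    def test_results_shape(self, fitted):
        assert set(fitted.transforms) == {"SDNN", "RMSSD", "LF", "HR", "ANI"}
        assert len(fitted.univariate) == 5
        assert (fitted.selection_trace.frequencies >= 0).all()
        assert (fitted.selection_trace.frequencies <= 1).all()
        assert isinstance(fitted.summary(), str)

    def test_classify_and_exclusions(self, fitted):
        rep = fitted.classify()
        assert rep.threshold == 0.39
        assert 0 < rep.auroc <= 1
        se_all = rep.sensitivity
        se_excl = rep.sensitivity_excluding(0)
        assert 0 <= se_excl <= 1 and 0 <= se_all <= 1

    def test_tree_class(self, study_table):
        res = ArousalTree(study_table, ["SDNN", "RMSSD", "LF", "HR", "ANI"]).fit()
        rep = res.classify()
        assert rep.tp + rep.fn == 70 and rep.tn + rep.fp == 138
        assert "leaf" in res.summary()
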