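"""PCA/varimax, Pearson screening, selection rules and VIF."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hrvarousal.config import FEATURE_NAMES
from hrvarousal.pipeline import ALWAYS_KEEP, DOMAIN_PREFS
from hrvarousal.selection import (
    FactorModel,
    SelectionRules,
    pca_varimax,
    pearson_matrix,
    select_uncorrelated,
    varimax,
    vif,
)


def make_block_table(n=2000, seed=0) -> pd.DataFrame:
    """Three orthogonal latent factors driving the study's variable blocks."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((n, 3))
    blocks = {
        "SDNN": 0, "RMSSD": 0, "LTV": 0, "STV": 0,
        "LF": 1, "HF": 1,
        "HR": 2, "ANI": 2,
    }
    data = {
        v: 0.9 * f[:, b] + 0.35 * rng.standard_normal(n) for v, b in blocks.items()
    }
    return pd.DataFrame(data), blocks


class TestPearson:
    def test_self_correlation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 5, 4]})
        m = pearson_matrix(df, ["x", "y"])
        assert m.loc["x", "x"] == pytest.approx(1.0)

    def test_anticorrelation(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4]})
        df["y"] = -df["x"]
        m = pearson_matrix(df, ["x", "y"])
        assert m.loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_example(self):
        # hand computation: cov = 7/6, var_x = 5/3, var_y = 19/12 -> r = 0.7182
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 5, 4]})
        m = pearson_matrix(df, ["x", "y"])
        expected = (7.0 / 6.0) / np.sqrt((5.0 / 3.0) * (19.0 / 12.0))
        assert m.loc["x", "y"] == pytest.approx(expected)
        assert m.loc["x", "y"] == pytest.approx(0.7182, abs=1e-4)

    def test_zero_variance_named(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "z": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="z"):
            pearson_matrix(df, ["x", "z"])

    def test_needs_three_rows(self):
        df = pd.DataFrame({"x": [1.0, 2], "y": [3.0, 1]})
        with pytest.raises(ValueError, match="3"):
            pearson_matrix(df, ["x", "y"])


class TestVarimax:
    def test_rotation_orthonormal(self, rng):
        L = rng.normal(size=(8, 3))
        _, R, _ = varimax(L)
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-10)

    def test_criterion_non_decreasing(self, rng):
        for _ in range(5):
            L = rng.normal(size=(10, 4))
            _, _, traj = varimax(L)
            assert all(b >= a - 1e-9 for a, b in zip(traj, traj[1:]))

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.multivariate.factor_rotation import rotate_factors

        for _ in range(3):
            L = rng.normal(size=(8, 3))
            ours, _, _ = varimax(L, kaiser_normalize=False)
            theirs, _ = rotate_factors(L, "varimax")
            # same solution up to column permutation, sign and convergence tol
            assert np.allclose(
                np.sort(np.abs(ours).ravel()), np.sort(np.abs(theirs).ravel()), atol=2e-3
            )

    def test_communalities_invariant(self):
        table, _ = make_block_table()
        fm = pca_varimax(table, list(table.columns), n_factors=3)
        before = (fm.unrotated**2).sum(axis=1)
        after = fm.communalities()
        assert np.allclose(before, after, atol=1e-8)


class TestPCAVarimax:
    def test_recovers_block_structure(self):
        table, blocks = make_block_table()
        fm = pca_varimax(table, list(table.columns), n_factors=3)
        dom = fm.dominant_factor(0.6)
        # all variables attributed, block members share a factor
        assert (dom >= 0).all()
        for b in range(3):
            members = [v for v, bb in blocks.items() if bb == b]
            assert dom[members].nunique() == 1
            for v in members:
                assert fm.loadings.loc[v].abs().max() > 0.6
                assert sorted(fm.loadings.loc[v].abs())[-2] < 0.4  # cross-loading

    def test_kaiser_rule_finds_three(self):
        table, _ = make_block_table()
        fm = pca_varimax(table, list(table.columns))
        assert fm.n_factors == 3

    def test_deterministic_signs(self):
        table, _ = make_block_table()
        a = pca_varimax(table, list(table.columns), n_factors=3)
        b = pca_varimax(table, list(table.columns), n_factors=3)
        assert np.allclose(a.loadings.to_numpy(), b.loadings.to_numpy())
        for c in a.loadings.columns:
            assert a.loadings[c].iloc[a.loadings[c].abs().argmax()] > 0

    def test_singular_matrix_error(self):
        df = pd.DataFrame({"x": np.arange(20.0)})
        df["y"] = 2 * df["x"]
        df["z"] = np.random.default_rng(0).normal(size=20)
        with pytest.raises(np.linalg.LinAlgError):
            pca_varimax(df, ["x", "y", "z"], n_factors=2)

    def test_too_few_rows(self):
        df = pd.DataFrame(np.eye(3), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            pca_varimax(df, ["a", "b", "c"])


class TestSelectUncorrelated:
    def test_study_pattern_yields_five(self, study_table):
        corr = pearson_matrix(study_table, list(FEATURE_NAMES))
        fm = pca_varimax(study_table, list(FEATURE_NAMES))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected, rules = select_uncorrelated(
                fm, corr, domain_prefs=DOMAIN_PREFS, always_keep=ALWAYS_KEEP
            )
        assert set(selected) == {"SDNN", "RMSSD", "LF", "HR", "ANI"}
        assert set(rules.drop_log) == {"LTV", "STV", "HF"}

    def test_all_uncorrelated_all_kept(self, rng):
        n = 3000
        df = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        corr = pearson_matrix(df, list("abcd"))
        fm = pca_varimax(df, list("abcd"), n_factors=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected, _ = select_uncorrelated(fm, corr)
        assert set(selected) == set("abcd")

    def test_duplicate_variable_dropped(self, rng):
        n = 500
        x = rng.standard_normal(n)
        df = pd.DataFrame({"x1": x, "x2": x + 1e-3 * rng.standard_normal(n),
                           "w": rng.standard_normal(n)})
        corr = pearson_matrix(df, ["x1", "x2", "w"])
        fm = pca_varimax(df, ["x1", "x2", "w"], n_factors=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selected, rules = select_uncorrelated(fm, corr, domain_prefs=["x1"])
        assert "x1" in selected and "x2" not in selected
        assert "x2" in rules.drop_log

    def test_unloaded_variable_warns_and_keeps(self):
        loadings = pd.DataFrame(
            {"factor1": [0.9, 0.85, 0.1]}, index=["a", "b", "c"]
        )
        fm = FactorModel(loadings, np.eye(1), np.array([1.6]), loadings.copy())
        corr = pd.DataFrame(np.eye(3), index=["a", "b", "c"], columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="c loads on no factor"):
            selected, _ = select_uncorrelated(fm, corr, domain_prefs=["a"])
        assert "c" in selected

    def test_order_invariance(self, study_table):
        corr = pearson_matrix(study_table, list(FEATURE_NAMES))
        fm = pca_varimax(study_table, list(FEATURE_NAMES))
        shuffled = list(FEATURE_NAMES)[::-1]
        fm2 = pca_varimax(study_table, shuffled)
        corr2 = pearson_matrix(study_table, shuffled)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a, _ = select_uncorrelated(fm, corr, domain_prefs=DOMAIN_PREFS,
                                       always_keep=ALWAYS_KEEP)
            b, _ = select_uncorrelated(fm2, corr2, domain_prefs=DOMAIN_PREFS,
                                       always_keep=ALWAYS_KEEP)
        assert set(a) == set(b)

    def test_cutoff_validation(self):
        with pytest.raises(ValueError):
            SelectionRules(loading_cutoff=1.5)


class TestVIF:
    def test_independent_near_one(self, rng):
        df = pd.DataFrame(rng.standard_normal((5000, 4)), columns=list("abcd"))
        v = vif(df, list("abcd"))
        assert ((v > 0.99) & (v < 1.1)).all()

    def test_duplicate_infinite(self, rng):
        x = rng.standard_normal(100)
        df = pd.DataFrame({"x": x, "y": x, "z": rng.standard_normal(100)})
        v = vif(df, ["x", "y", "z"])
        assert np.isinf(v["x"]) and np.isinf(v["y"])

    def test_at_least_one(self, rng):
        df = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        df["b"] = df["a"] * 0.5 + df["b"]
        assert (vif(df, list("abc")) >= 1.0 - 1e-12).all()
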