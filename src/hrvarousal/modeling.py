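"""Prediction models for "BIS>=60" periods and their classification reports.

Two models are provided, in a statsmodels-like shape (a model object built
from the measurement table whose ``fit()`` returns a results object):

* :class:`ArousalLogit` — univariate screening, restricted-cubic-spline
  log-linearity checks (variables failing the check are log-transformed),
  VIF collinearity check, bootstrap-stepwise backward selection (500
  resamples, Wald-p removal at 0.05, 70% retention) and a final
  maximum-likelihood logistic fit with odds ratios and Wald CIs.
* :class:`ArousalTree` — CART: greedy binary recursive partitioning on Gini
  impurity with midpoint thresholds and deterministic tie-breaking (declared
  variable order, then smaller threshold).

Both results objects produce a :class:`ClassificationReport` with confusion
counts, Se/Sp/PPV/NPV, AUROC with a DeLong 95% CI, and the per-time-point
misclassification breakdown (including the sensitivity recomputed with the
T0 rows excluded, since most false negatives occur at the crossing itself).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .config import NEGATIVE_LABEL, POSITIVE_LABEL, AnalysisConfig
from .selection import vif as _vif


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def _fmt(x: float, nd: int = 2) -> str:
    s = f"{x:.{nd}f}".rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


def summarize(table: pd.DataFrame, variables: list[str], mode: str = "auto",
              alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable descriptive summary.

    Quantitative variables are shown as mean +- sd when a Shapiro-Wilk test
    does not reject normality (or always, with ``mode='mean'``) and as
    median [IQR] otherwise; categorical variables as count/total (%).
    """
    rows = []
    for v in variables:
        col = table[v].dropna()
        if col.dtype == object or col.dtype.name in ("category", "bool"):
            for level, k in col.value_counts().items():
                rows.append(
                    {
                        "variable": f"{v}={level}",
                        "kind": "categorical",
                        "display": f"{k}/{len(col)} ({100 * k / len(col):.2f})",
                    }
                )
            continue
        x = col.to_numpy(float)
        if mode == "auto":
            normal = len(x) >= 3 and np.std(x) > 0 and st.shapiro(x).pvalue >= alpha
        else:
            normal = mode == "mean"
        if normal:
            disp = f"{_fmt(x.mean())} ± {_fmt(x.std(ddof=1))}"
            kind = "mean_sd"
        else:
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            disp = f"{_fmt(med)} [{_fmt(q1)}–{_fmt(q3)}]"
            kind = "median_iqr"
        rows.append({"variable": v, "kind": kind, "display": disp})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic building blocks
# ---------------------------------------------------------------------------

def _binary_response(table: pd.DataFrame) -> np.ndarray:
    y = (table["class"] == POSITIVE_LABEL).to_numpy(float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y


def _design(table: pd.DataFrame, variables: list[str],
            transforms: dict[str, str] | None = None) -> pd.DataFrame:
    transforms = transforms or {}
    cols = {}
    for v in variables:
        x = table[v].to_numpy(float)
        if transforms.get(v, "identity") == "log":
            if np.any(x <= 0):
                raise ValueError(f"log transform of {v} requires positive values")
            cols[f"log({v})"] = np.log(x)
        else:
            cols[v] = x
    X = pd.DataFrame(cols, index=table.index)
    return sm.add_constant(X, has_constant="add")


@dataclass
class LogisticModel:
    """A fitted logistic model of the positive ("BIS>=60") class."""

    variables: list[str]
    transforms: dict[str, str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    llf: float
    n_obs: int

    @property
    def odds_ratios(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "ci_low": np.exp(self.conf_int[0]),
                "ci_high": np.exp(self.conf_int[1]),
                "p": self.pvalues,
            }
        )
        return out.drop(index="const")

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = _design(table, self.variables, self.transforms)[self.params.index]
        eta = X.to_numpy(float) @ self.params.to_numpy(float)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(
    table: pd.DataFrame,
    variables: list[str],
    transforms: dict[str, str] | None = None,
) -> LogisticModel:
    """Maximum-likelihood logistic fit of class on the (transformed) variables."""
    data = table.dropna(subset=list(variables) + ["class"]) if variables else table
    y = _binary_response(data)
    if variables and len(data) <= len(variables):
        raise ValueError("need more rows than variables")
    X = _design(data, variables, transforms)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise ValueError("perfect separation: logistic MLE does not exist") from exc
    if not res.mle_retvals.get("converged", True):
        raise ValueError(
            f"logistic fit did not converge in {res.mle_retvals.get('iterations')} iterations"
        )
    return LogisticModel(
        variables=list(variables),
        transforms=dict(transforms or {}),
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        conf_int=res.conf_int(),
        llf=float(res.llf),
        n_obs=len(data),
    )


# ---------------------------------------------------------------------------
# restricted cubic splines
# ---------------------------------------------------------------------------

def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear tails): columns x, C_1..C_{k-2}."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        cj = (
            np.clip(x - t[j], 0, None) ** 3
            - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
            + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(cj / norm)
    return np.column_stack(cols)


def spline_loglinearity_test(
    table: pd.DataFrame,
    variable: str,
    knot_quantiles: tuple[float, ...] = (0.05, 0.35, 0.65, 0.95),
    alpha: float = 0.05,
) -> dict:
    """Likelihood-ratio test of spline vs linear logit term.

    Fits the logistic model with restricted-cubic-spline terms for
    ``variable`` against the model with the linear term only; a small
    p-value rejects log-linearity and marks the variable for log transform.
    When either model is not estimable (quasi-separation on a small sample
    makes the Hessian singular) the test is inconclusive and the identity
    transform is kept, with ``p`` reported as NaN.
    """
    data = table.dropna(subset=[variable, "class"])
    if len(data) < 30:
        raise ValueError("need at least 30 rows")
    y = _binary_response(data)
    x = data[variable].to_numpy(float)
    knots = np.quantile(x, knot_quantiles)
    if len(np.unique(knots)) < len(knots):
        raise ValueError(f"degenerate spline knots for {variable}")
    B = rcs_basis(x, knots)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(y, sm.add_constant(B)).fit(disp=0, maxiter=200)
            lin = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, PerfectSeparationError):
        return {
            "variable": variable,
            "lr_statistic": float("nan"),
            "df": B.shape[1] - 1,
            "p": float("nan"),
            "transform": "identity",
        }
    lr = max(0.0, 2.0 * (full.llf - lin.llf))
    df = B.shape[1] - 1
    p = float(st.chi2.sf(lr, df))
    return {
        "variable": variable,
        "lr_statistic": lr,
        "df": df,
        "p": p,
        "transform": "log" if p < alpha else "identity",
    }


# ---------------------------------------------------------------------------
# AUROC with DeLong CI
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return st.rankdata(x, method="average")


def auroc(scores, labels, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """AUROC (Mann-Whitney, ties counted 1/2) with a DeLong Wald CI.

    ``labels`` may be booleans, 0/1, or the study's class strings.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "US" or (
        labels.dtype.kind == "O" and labels.size and isinstance(labels.flat[0], str)
    ):
        y = labels == POSITIVE_LABEL
    else:
        y = labels.astype(bool)
    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(scores)
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[y].sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[y] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[~y] - neg_ranks) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = st.norm.ppf(0.5 + level / 2)
    lo, hi = float(np.clip(auc - z * se, 0, 1)), float(np.clip(auc + z * se, 0, 1))
    return float(auc), (lo, hi)


# ---------------------------------------------------------------------------
# classification report
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Confusion counts, derived metrics and per-time-point misclassification.

    ``by_timepoint`` (optional) has one row per time point with columns
    ``n_pos, n_neg, fn, fp`` — ``fn`` are positives classified negative,
    ``fp`` negatives classified positive; the rows partition the totals.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float | None = None
    auroc: float | None = None
    auroc_ci: tuple[float, float] | None = None
    by_timepoint: pd.DataFrame | None = None

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    def _tp_row(self, timepoint: int) -> pd.Series:
        if self.by_timepoint is None:
            raise ValueError("no per-time-point breakdown available")
        sub = self.by_timepoint[self.by_timepoint["timepoint_min"] == timepoint]
        if sub.empty:
            raise KeyError(f"no rows at time point {timepoint}")
        return sub.iloc[0]

    def sensitivity_excluding(self, timepoint: int = 0) -> float:
        """Sensitivity recomputed with one time point's rows removed."""
        row = self._tp_row(timepoint)
        tp = self.tp - (row["n_pos"] - row["fn"])
        fn = self.fn - row["fn"]
        return tp / (tp + fn)

    def specificity_excluding(self, timepoint: int = 0) -> float:
        row = self._tp_row(timepoint)
        tn = self.tn - (row["n_neg"] - row["fp"])
        fp = self.fp - row["fp"]
        return tn / (tn + fp)

    def sensitivity_at(self, timepoint: int) -> float:
        """Sensitivity within a single time point's rows."""
        row = self._tp_row(timepoint)
        return (row["n_pos"] - row["fn"]) / row["n_pos"]

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int,
                    by_timepoint: pd.DataFrame | None = None,
                    threshold: float | None = None) -> "ClassificationReport":
        """Build a report from stated confusion counts (no score data)."""
        if by_timepoint is not None:
            if int(by_timepoint["fn"].sum()) != fn or int(by_timepoint["fp"].sum()) != fp:
                raise ValueError("per-time-point rows must sum to FN and FP")
        return cls(tp=tp, fp=fp, tn=tn, fn=fn, threshold=threshold,
                   by_timepoint=by_timepoint)

    @classmethod
    def from_predictions(
        cls,
        table: pd.DataFrame,
        predicted_positive: np.ndarray,
        scores: np.ndarray | None = None,
        threshold: float | None = None,
    ) -> "ClassificationReport":
        y = table["class"].to_numpy() == POSITIVE_LABEL
        yhat = np.asarray(predicted_positive, dtype=bool)
        tp = int(np.sum(y & yhat))
        fp = int(np.sum(~y & yhat))
        tn = int(np.sum(~y & ~yhat))
        fn = int(np.sum(y & ~yhat))
        by_tp = None
        if "timepoint_min" in table.columns:
            rows = []
            for t in sorted(table["timepoint_min"].unique()):
                sel = (table["timepoint_min"] == t).to_numpy()
                rows.append(
                    {
                        "timepoint_min": int(t),
                        "n_pos": int(np.sum(y & sel)),
                        "n_neg": int(np.sum(~y & sel)),
                        "fn": int(np.sum(y & sel & ~yhat)),
                        "fp": int(np.sum(~y & sel & yhat)),
                    }
                )
            by_tp = pd.DataFrame(rows)
        auc = ci = None
        if scores is not None:
            auc, ci = auroc(scores, y)
        return cls(tp=tp, fp=fp, tn=tn, fn=fn, threshold=threshold,
                   auroc=auc, auroc_ci=ci, by_timepoint=by_tp)

    def metrics(self) -> dict[str, float]:
        out = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }
        if self.auroc is not None:
            out["auroc"] = self.auroc
        return out

    def summary(self) -> str:
        lines = [
            f"TP={self.tp}  FP={self.fp}  TN={self.tn}  FN={self.fn}",
            f"Se={self.sensitivity:.2f}  Sp={self.specificity:.2f}  "
            f"PPV={self.ppv:.2f}  NPV={self.npv:.2f}",
        ]
        if self.auroc is not None:
            lo, hi = self.auroc_ci
            lines.append(f"AUROC={self.auroc:.2f} [{lo:.2f}-{hi:.2f}]")
        if self.by_timepoint is not None:
            lines.append("misclassified by time point:")
            lines.append(self.by_timepoint.to_string(index=False))
            if (self.by_timepoint["timepoint_min"] == 0).any():
                lines.append(
                    f"Se excluding T0: {self.sensitivity_excluding(0):.2f}"
                )
        return "\n".join(lines)


def classify(model: LogisticModel, table: pd.DataFrame, threshold: float = 0.39
             ) -> ClassificationReport:
    """Threshold the fitted probabilities and report classification metrics."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    data = table.dropna(subset=model.variables + ["class"])
    p = model.predict(data)
    return ClassificationReport.from_predictions(
        data, p >= threshold, scores=p, threshold=threshold
    )


def youden_threshold(scores: np.ndarray, labels) -> float:
    """Probability threshold maximizing Se + Sp - 1 (ties -> smaller threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == POSITIVE_LABEL if labels.dtype.kind in "US" else labels.astype(bool)
    best_j, best_t = -np.inf, None
    for t in np.unique(scores):
        yhat = scores >= t
        se = np.sum(y & yhat) / y.sum()
        sp = np.sum(~y & ~yhat) / (~y).sum()
        j = se + sp - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


# ---------------------------------------------------------------------------
# bootstrap stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionTrace:
    """Bootstrap-stepwise selection bookkeeping."""

    frequencies: pd.Series
    retained: list[str]
    B: int
    removal_alpha: float
    retention_threshold: float
    replicate_sets: list[tuple[str, ...]] = field(repr=False, default_factory=list)
    n_redraws: int = 0


def _backward_select(table: pd.DataFrame, candidates: list[str],
                     transforms: dict[str, str], alpha: float) -> list[str]:
    current = list(candidates)
    while current:
        model = fit_logistic(table, current, transforms)
        pvals = model.pvalues.drop(index="const")
        worst = pvals.idxmax()
        if pvals[worst] <= alpha:
            break
        # map the design column name back to the variable
        name = worst[4:-1] if worst.startswith("log(") else worst
        current = [v for v in current if v != name]
    return current


def bootstrap_stepwise_select(
    table: pd.DataFrame,
    candidates: list[str],
    B: int = 500,
    removal_alpha: float = 0.05,
    retention_threshold: float = 0.70,
    seed: int = 0,
    transforms: dict[str, str] | None = None,
) -> SelectionTrace:
    """Backward-stepwise logistic selection over case-level bootstrap resamples.

    Each replicate resamples cases (rows grouped by ``case_id``) with
    replacement, fits the full logistic model and iteratively removes the
    variable with the largest Wald p until all p <= ``removal_alpha``.
    Variables selected in at least ``retention_threshold`` of the replicates
    form the retained set. Replicates with a single class (or a failed fit)
    are redrawn; more than 20% redraws aborts.
    """
    if B < 1 or not candidates:
        raise ValueError("need B >= 1 and at least one candidate")
    transforms = dict(transforms or {})
    data = table.dropna(subset=list(candidates) + ["class"]).reset_index(drop=True)
    if "case_id" in data.columns:
        groups = {cid: idx.to_numpy() for cid, idx in data.groupby("case_id").groups.items()}
    else:
        groups = {i: np.array([i]) for i in range(len(data))}
    case_ids = sorted(groups)
    rng = np.random.default_rng(seed)
    counts = {v: 0 for v in sorted(candidates)}
    sets: list[tuple[str, ...]] = []
    redraws = 0
    max_redraws = max(1, int(0.2 * B))
    b = 0
    while b < B:
        draw = rng.choice(len(case_ids), size=len(case_ids), replace=True)
        idx = np.concatenate([groups[case_ids[i]] for i in draw])
        sample = data.iloc[idx]
        try:
            kept = _backward_select(sample, sorted(candidates), transforms, removal_alpha)
        except ValueError:
            redraws += 1
            if redraws > max_redraws:
                raise ValueError(
                    f"more than 20% of bootstrap replicates were degenerate ({redraws})"
                )
            continue
        for v in kept:
            counts[v] += 1
        sets.append(tuple(kept))
        b += 1
    freq = pd.Series({v: counts[v] / B for v in sorted(candidates)}, name="frequency")
    retained = [v for v in candidates if freq[v] >= retention_threshold]
    return SelectionTrace(freq, retained, B, removal_alpha, retention_threshold,
                          sets, redraws)


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    n_pos: int
    n_neg: int
    variable: str | None = None     # None for leaves
    threshold: float | None = None
    left: "TreeNode | None" = None  # rows with x < threshold
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def predicted(self) -> str:
        # majority class; ties go to the negative (majority-prevalence) class
        return POSITIVE_LABEL if self.n_pos > self.n_neg else NEGATIVE_LABEL

    def gini(self) -> float:
        if self.n == 0:
            return 0.0
        p = self.n_pos / self.n
        return 2.0 * p * (1.0 - p)


@dataclass
class TreeModel:
    root: TreeNode
    variables: list[str]
    min_split: int
    min_leaf: int
    min_improvement: float

    def predict_row(self, row: pd.Series) -> str:
        node = self.root
        while not node.is_leaf:
            x = row[node.variable]
            if pd.isna(x):
                raise ValueError(f"missing value for split variable {node.variable}")
            node = node.left if x < node.threshold else node.right
        return node.predicted

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return np.array([self.predict_row(r) for _, r in table.iterrows()])

    def depth(self) -> int:
        def d(node: TreeNode) -> int:
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))
        return d(self.root)

    def summary(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, indent: int, prefix: str) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(
                    f"{pad}{prefix}leaf -> {node.predicted} "
                    f"({node.n_pos} | {node.n_neg})"
                )
            else:
                lines.append(
                    f"{pad}{prefix}{node.variable} < {node.threshold:g} "
                    f"({node.n_pos} | {node.n_neg})"
                )
                walk(node.left, indent + 1, "yes: ")
                walk(node.right, indent + 1, "no:  ")

        walk(self.root, 0, "")
        return "\n".join(lines)


def _gini_counts(n_pos: int, n_neg: int) -> float:
    n = n_pos + n_neg
    if n == 0:
        return 0.0
    p = n_pos / n
    return 2.0 * p * (1.0 - p)


def best_split(table: pd.DataFrame, variables: list[str], y: np.ndarray,
               min_leaf: int = 1) -> tuple[str, float, float] | None:
    """Exhaustively best (variable, midpoint threshold, Gini gain) for a node.

    Ties are broken by declared variable order, then by smaller threshold.
    Returns None when no admissible split exists.
    """
    n = len(y)
    parent = _gini_counts(int(y.sum()), int(n - y.sum()))
    best: tuple[str, float, float] | None = None
    for v in variables:
        x = table[v].to_numpy(float)
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        distinct = np.flatnonzero(np.diff(xs) > 0)
        if distinct.size == 0:
            continue
        cum_pos = np.cumsum(ys)
        for i in distinct:
            nl = i + 1
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            lp = int(cum_pos[i])
            rp = int(cum_pos[-1] - cum_pos[i])
            gain = parent - (
                nl / n * _gini_counts(lp, nl - lp) + nr / n * _gini_counts(rp, nr - rp)
            )
            thr = (xs[i] + xs[i + 1]) / 2.0
            if best is None or gain > best[2] + 1e-12:
                best = (v, thr, gain)
    return best


def fit_cart(
    table: pd.DataFrame,
    variables: list[str],
    min_split: int = 20,
    min_leaf: int = 7,
    min_improvement: float = 0.01,
) -> TreeModel:
    """Greedy Gini-impurity CART on the measurement table.

    A split is accepted when its root-share-weighted impurity decrease,
    ``(n_node / n_root) * gain``, is at least ``min_improvement`` times the
    root impurity (the usual complexity-parameter convention in recursive
    partitioning).
    """
    data = table.dropna(subset=list(variables) + ["class"])
    if data.empty:
        raise ValueError("empty table")
    y_all = (data["class"] == POSITIVE_LABEL).to_numpy()
    n_root = len(data)
    root_gini = _gini_counts(int(y_all.sum()), int(n_root - y_all.sum()))

    def build(sub: pd.DataFrame, y: np.ndarray) -> TreeNode:
        node = TreeNode(n_pos=int(y.sum()), n_neg=int(len(y) - y.sum()))
        if node.n < min_split or node.n_pos == 0 or node.n_neg == 0:
            return node
        found = best_split(sub, variables, y, min_leaf)
        if found is None:
            return node
        v, thr, gain = found
        if root_gini > 0 and (node.n / n_root) * gain < min_improvement * root_gini:
            return node
        mask = sub[v].to_numpy(float) < thr
        node.variable, node.threshold = v, thr
        node.left = build(sub[mask], y[mask])
        node.right = build(sub[~mask], y[~mask])
        return node

    root = build(data, y_all)
    return TreeModel(root, list(variables), min_split, min_leaf, min_improvement)


def predict_tree(tree: TreeModel, table: pd.DataFrame) -> ClassificationReport:
    """Route rows through the tree and report classification metrics."""
    data = table.dropna(subset=["class"])
    labels = tree.predict(data)
    return ClassificationReport.from_predictions(data, labels == POSITIVE_LABEL)


# ---------------------------------------------------------------------------
# statsmodels-style model / results objects
# ---------------------------------------------------------------------------

class ArousalLogit:
    """Bootstrap-stepwise logistic model of "BIS>=60" measurement periods.

    Parameters
    ----------
    table : DataFrame
        Measurement table with one row per case x time point, the candidate
        predictor columns, and a ``class`` column ("BIS>=60"/"BIS<60").
    candidates : list of str
        Candidate predictors (the study's uncorrelated set:
        SDNN, RMSSD, LF, HR, ANI).
    config : AnalysisConfig
        Selection/fit constants; defaults reproduce the study design.
    """

    def __init__(self, table: pd.DataFrame, candidates: list[str],
                 config: AnalysisConfig | None = None):
        self.table = table.dropna(subset=list(candidates) + ["class"]).reset_index(drop=True)
        self.candidates = list(candidates)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_measurements(cls, table: pd.DataFrame, candidates: list[str] | None = None,
                          config: AnalysisConfig | None = None) -> "ArousalLogit":
        candidates = candidates or ["SDNN", "RMSSD", "LF", "HR", "ANI"]
        return cls(table, candidates, config)

    def fit(self, seed: int | None = None) -> "ArousalLogitResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        spline_tests = {
            v: spline_loglinearity_test(self.table, v, cfg.spline_knot_quantiles, cfg.alpha)
            for v in self.candidates
        }
        transforms = {v: t["transform"] for v, t in spline_tests.items()}
        vifs = _vif(self.table, self.candidates)
        univariate = {}
        labels = self.table["class"].to_numpy()
        for v in self.candidates:
            try:
                m = fit_logistic(self.table, [v], {v: transforms[v]})
                scores = m.predict(self.table)
            except ValueError:
                # perfectly separating variable: its OR is not estimable, but
                # the AUROC is link-free (use the orientation with AUC >= 0.5)
                m = None
                scores = self.table[v].to_numpy(float)
                if auroc(scores, labels)[0] < 0.5:
                    scores = -scores
            auc, ci = auroc(scores, labels)
            univariate[v] = {"model": m, "auroc": auc, "auroc_ci": ci}
        trace = bootstrap_stepwise_select(
            self.table,
            self.candidates,
            B=cfg.bootstrap_replicates,
            removal_alpha=cfg.removal_alpha,
            retention_threshold=cfg.retention_threshold,
            seed=seed,
            transforms=transforms,
        )
        final = fit_logistic(self.table, trace.retained, transforms) if trace.retained else None
        return ArousalLogitResults(self, spline_tests, transforms, vifs,
                                   univariate, trace, final)


class ArousalLogitResults:
    """Results of :meth:`ArousalLogit.fit`."""

    def __init__(self, model: ArousalLogit, spline_tests, transforms, vifs,
                 univariate, selection_trace: SelectionTrace,
                 final: LogisticModel | None):
        self.model = model
        self.spline_tests = spline_tests
        self.transforms = transforms
        self.vif = vifs
        self.univariate = univariate
        self.selection_trace = selection_trace
        self.final = final

    @property
    def retained(self) -> list[str]:
        return self.selection_trace.retained

    def predict(self, table: pd.DataFrame | None = None) -> np.ndarray:
        if self.final is None:
            raise ValueError("no variable was retained; there is no final model")
        return self.final.predict(self.model.table if table is None else table)

    def classify(self, threshold: float | None = None,
                 table: pd.DataFrame | None = None) -> ClassificationReport:
        if self.final is None:
            raise ValueError("no variable was retained; there is no final model")
        threshold = self.model.config.classification_threshold if threshold is None else threshold
        return classify(self.final, self.model.table if table is None else table, threshold)

    def summary(self) -> str:
        lines = ["Bootstrap-stepwise logistic model of BIS>=60 periods", ""]
        lines.append("log-linearity (LR spline test) and transforms:")
        for v, t in self.spline_tests.items():
            lines.append(f"  {v}: p={t['p']:.3f} -> {t['transform']}")
        lines.append("")
        lines.append("VIF: " + ", ".join(f"{v}={x:.2f}" for v, x in self.vif.items()))
        lines.append("")
        lines.append("univariate AUROCs:")
        for v, u in self.univariate.items():
            lo, hi = u["auroc_ci"]
            lines.append(f"  {v}: {u['auroc']:.2f} [{lo:.2f}-{hi:.2f}]")
        lines.append("")
        lines.append(
            f"bootstrap retention (B={self.selection_trace.B}, "
            f"threshold {self.selection_trace.retention_threshold}):"
        )
        for v, f in self.selection_trace.frequencies.items():
            mark = "*" if v in self.retained else " "
            lines.append(f" {mark} {v}: {f:.2f}")
        lines.append("")
        if self.final is not None:
            lines.append("final model odds ratios:")
            orr = self.final.odds_ratios
            for name, row in orr.iterrows():
                lines.append(
                    f"  {name}: OR {row['OR']:.2f} "
                    f"[{row['ci_low']:.2f}-{row['ci_high']:.2f}] p={row['p']:.3g}"
                )
            rep = self.classify()
            lines.append("")
            lines.append(rep.summary())
        else:
            lines.append("no variable retained by the bootstrap-stepwise rule")
        return "\n".join(lines)


class ArousalTree:
    """CART model of "BIS>=60" measurement periods."""

    def __init__(self, table: pd.DataFrame, candidates: list[str],
                 config: AnalysisConfig | None = None):
        self.table = table.dropna(subset=list(candidates) + ["class"]).reset_index(drop=True)
        self.candidates = list(candidates)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_measurements(cls, table: pd.DataFrame, candidates: list[str] | None = None,
                          config: AnalysisConfig | None = None) -> "ArousalTree":
        candidates = candidates or ["SDNN", "RMSSD", "LF", "HR", "ANI"]
        return cls(table, candidates, config)

    def fit(self) -> "ArousalTreeResults":
        cfg = self.config
        tree = fit_cart(
            self.table,
            self.candidates,
            min_split=cfg.cart_min_split,
            min_leaf=cfg.cart_min_leaf,
            min_improvement=cfg.cart_min_improvement,
        )
        return ArousalTreeResults(self, tree)


class ArousalTreeResults:
    def __init__(self, model: ArousalTree, tree: TreeModel):
        self.model = model
        self.tree = tree

    def classify(self, table: pd.DataFrame | None = None) -> ClassificationReport:
        return predict_tree(self.tree, self.model.table if table is None else table)

    def summary(self) -> str:
        rep = self.classify()
        return "CART model of BIS>=60 periods\n\n" + self.tree.summary() + "\n\n" + rep.summary()
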