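"""Candidate-predictor screening: PCA with varimax rotation, Pearson
correlation screening and collinearity (VIF) checks.

The eight HRV variables are grouped by their dominant rotated factor
(|loading| > 0.6); within a group, a preference-ranked representative is
kept and variables correlated with it above |r| = 0.70 are dropped, unless
explicitly preference-retained. The preference ordering encodes the
clinical/physiological reasoning that cannot be automated (e.g. SDNN is
kept over the fetal-monitoring indices LTV and STV; RMSSD is kept despite
its correlation with SDNN because it tracks a distinct autonomic pathway).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor


def pearson_matrix(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Pairwise Pearson correlations on complete cases."""
    data = table[variables].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows")
    sd = data.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance variable(s): {zero}")
    return data.corr(method="pearson")


# ---------------------------------------------------------------------------
# PCA + varimax
# ---------------------------------------------------------------------------

@dataclass
class FactorModel:
    """Rotated principal-factor loadings."""

    loadings: pd.DataFrame          # variables x factors, rotated
    rotation: np.ndarray            # orthonormal rotation applied
    explained_variance: np.ndarray  # per rotated factor (sum of squared loadings)
    unrotated: pd.DataFrame

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)

    def dominant_factor(self, cutoff: float = 0.6) -> pd.Series:
        """Index of the factor each variable loads on above ``cutoff`` (-1: none)."""
        absl = self.loadings.abs()
        dom = absl.values.argmax(axis=1)
        ok = absl.values.max(axis=1) > cutoff
        return pd.Series(np.where(ok, dom, -1), index=self.loadings.index)


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            tol: float = 1e-7, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Varimax rotation (SVD algorithm), optionally Kaiser-normalized.

    Returns (rotated loadings, rotation matrix, criterion trajectory). The
    varimax criterion is non-decreasing across iterations.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    h = np.ones(p)
    if kaiser_normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
    A = L / h[:, None]
    R = np.eye(k)
    trajectory = []

    def criterion(B: np.ndarray) -> float:
        B2 = B**2
        return float(np.sum(B2**2) - np.sum(B2.sum(axis=0) ** 2) / p)

    d_old = 0.0
    for _ in range(max_iter):
        B = A @ R
        trajectory.append(criterion(B))
        u, s, vt = np.linalg.svd(
            A.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
        d_old = d
    rotated = (A @ R) * h[:, None]
    trajectory.append(criterion(rotated / h[:, None]))
    return rotated, R, trajectory


def pca_varimax(
    table: pd.DataFrame,
    variables: list[str],
    n_factors: int | None = None,
    reference_signs: pd.DataFrame | None = None,
) -> FactorModel:
    """PCA on standardized variables followed by varimax rotation.

    The PCA uses the correlation matrix (the variables have incommensurate
    units). ``n_factors`` defaults to the Kaiser rule (eigenvalues > 1).
    Factor signs are fixed so that each rotated factor's largest-|loading|
    entry is positive; ``reference_signs`` (a variables x factors frame of
    +-1) can override that to match a published pattern.
    """
    data = table[variables].dropna()
    if len(data) <= len(variables):
        raise ValueError("need more rows than variables")
    corr = pearson_matrix(data, variables).to_numpy()
    if np.linalg.matrix_rank(corr) < len(variables):
        raise np.linalg.LinAlgError("singular correlation matrix")
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if n_factors is None:
        n_factors = max(1, int(np.sum(eigval > 1.0)))
    if n_factors > len(variables):
        raise ValueError("n_factors cannot exceed the number of variables")
    L = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])
    rotated, R, _ = varimax(L)

    # deterministic sign convention
    for j in range(n_factors):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            rotated[:, j] = -rotated[:, j]
            R[:, j] = -R[:, j]
    cols = [f"factor{j + 1}" for j in range(n_factors)]
    loadings = pd.DataFrame(rotated, index=variables, columns=cols)
    if reference_signs is not None:
        for j, c in enumerate(cols):
            ref = reference_signs.reindex(loadings.index)[reference_signs.columns[j]]
            if (loadings[c] * ref).sum() < 0:
                loadings[c] = -loadings[c]
                R[:, j] = -R[:, j]
    unrot = pd.DataFrame(L, index=variables, columns=cols)
    explained = (loadings**2).sum(axis=0).to_numpy()
    return FactorModel(loadings, R, explained, unrot)


# ---------------------------------------------------------------------------
# selection rules
# ---------------------------------------------------------------------------

@dataclass
class SelectionRules:
    loading_cutoff: float = 0.6
    corr_cutoff: float = 0.70
    keep_list: list[str] = field(default_factory=list)
    drop_log: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.loading_cutoff < 1 and 0 < self.corr_cutoff < 1):
            raise ValueError("cutoffs must lie in (0, 1)")


def select_uncorrelated(
    fm: FactorModel,
    corr: pd.DataFrame,
    rules: SelectionRules | None = None,
    domain_prefs: list[str] | None = None,
    always_keep: set[str] | None = None,
) -> tuple[list[str], SelectionRules]:
    """Pick one low-correlation representative set from the factor groups.

    ``domain_prefs`` ranks variables (earlier = preferred within a factor
    group; unlisted variables rank after listed ones, by loading magnitude).
    ``always_keep`` marks variables retained even when correlated above the
    cutoff with an already-kept group member (the study keeps RMSSD despite
    r = 0.82 with SDNN, on physiological grounds). Variables that load on no
    factor above the cutoff are retained with a warning.
    """
    rules = rules or SelectionRules()
    domain_prefs = domain_prefs or []
    always_keep = always_keep or set()
    variables = list(fm.loadings.index)
    dom = fm.dominant_factor(rules.loading_cutoff)

    def rank(v: str) -> tuple:
        in_pref = v in domain_prefs
        return (
            0 if in_pref else 1,
            domain_prefs.index(v) if in_pref else 0,
            -abs(fm.loadings.loc[v]).max(),
        )

    kept: list[str] = []
    for f in sorted(dom.unique()):
        group = [v for v in variables if dom[v] == f]
        if f == -1:
            for v in group:
                warnings.warn(
                    f"{v} loads on no factor above {rules.loading_cutoff}; retained",
                    stacklevel=2,
                )
                kept.append(v)
            continue
        group = sorted(group, key=rank)
        group_kept: list[str] = []
        for v in group:
            if not group_kept:
                group_kept.append(v)
                continue
            if v in always_keep:
                group_kept.append(v)
                continue
            partner = next(
                (u for u in group_kept if abs(corr.loc[v, u]) > rules.corr_cutoff), None
            )
            if partner is not None:
                rules.drop_log[v] = (
                    f"|r|={abs(corr.loc[v, partner]):.2f} with retained {partner} "
                    f"> {rules.corr_cutoff}"
                )
            else:
                group_kept.append(v)
        kept.extend(group_kept)
    rules.keep_list = [v for v in variables if v in kept]
    return rules.keep_list, rules


def vif(table: pd.DataFrame, variables: list[str]) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    Perfect collinearity yields ``inf`` for the variables involved rather
    than an exception.
    """
    data = table[variables].dropna()
    if len(data) < len(variables) + 2:
        raise ValueError("need at least len(variables) + 2 complete rows")
    X = np.column_stack([np.ones(len(data)), data.to_numpy(float)])
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, v in enumerate(variables):
            val = variance_inflation_factor(X, j + 1)
            out[v] = float(val) if np.isfinite(val) else np.inf
    return pd.Series(out, name="VIF")
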