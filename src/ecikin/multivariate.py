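"""Exploratory multivariate linking of wood-structure descriptors to kinetics.

With only three toast levels as observations, the statistics here are
deliberately descriptive: standardized PCA on the toast-level × descriptor
matrix (with n = 3 observations the centered matrix has rank ≤ 2, so two
components carry 100% of the variance), Spearman rank correlations as
monotonicity descriptors (no p-values — meaningless at n = 3), and a
classical one-way ANOVA for comparing daily ECI distributions between
toast levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import DESCRIPTOR_ORDER

__all__ = [
    "PCAResult",
    "AnovaResult",
    "standardize",
    "run_pca",
    "spearman_rho",
    "spearman_matrix",
    "one_way_anova",
]


def standardize(m: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column to mean 0 and sample (n−1) standard deviation 1."""
    m = m.astype(float)
    sd = m.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-spread column(s): {list(zero.index)}")
    return (m - m.mean()) / sd


@dataclass(frozen=True)
class PCAResult:
    """Loadings (variables × PCs, orthonormal columns), scores and explained %."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_pct: np.ndarray


def run_pca(m: pd.DataFrame) -> PCAResult:
    """PCA of an already-standardized matrix via singular value decomposition.

    Keeps the min(rows − 1, columns) components that can be non-null for a
    centered matrix; explained percentages come from squared singular
    values and sum to 100.  Loading signs are fixed so each column's
    largest-magnitude entry is positive (PCA signs are otherwise
    arbitrary).
    """
    if m.shape[0] < 2:
        raise ValueError("PCA needs at least 2 observations")
    X = m.to_numpy(dtype=float)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(m.shape[0] - 1, m.shape[1])
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    flip = np.sign(Vt[np.arange(k), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    total = float(np.sum(S**2))
    explained = 100.0 * S**2 / total if total > 0 else np.zeros(k)
    pcs = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        loadings=pd.DataFrame(Vt.T, index=m.columns, columns=pcs),
        scores=pd.DataFrame(U * S, index=m.index, columns=pcs),
        explained_pct=explained,
    )


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if a rank variance is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with ≥ 2 values")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("Spearman rho undefined: zero rank variance", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(x, y).statistic
    return float(rho)


def spearman_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho over the columns of a descriptor matrix."""
    cols = list(m.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            r = spearman_rho(m.iloc[:, a], m.iloc[:, b])
            out.iloc[a, b] = out.iloc[b, a] = r
    return out


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA decomposition."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    degenerate: bool = False  # zero within-group variance


def one_way_anova(groups) -> AnovaResult:
    """Between/within decomposition with F and its upper-tail p-value.

    Zero within-group variance with nonzero between-group variance yields
    an infinite F flagged degenerate (p reported as 0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for idx, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {idx} has fewer than 2 values")
    n = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df_b = len(groups) - 1
    df_w = n - len(groups)
    ms_b = ss_between / df_b
    if ss_within == 0:
        if ss_between == 0:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        return AnovaResult(float("inf"), df_b, df_w, 0.0, degenerate=True)
    f = ms_b / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p)


def default_feature_columns() -> tuple[str, ...]:
    """The canonical descriptor-column order of the feature matrix."""
    return DESCRIPTOR_ORDER
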