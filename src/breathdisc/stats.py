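"""Inference statistics: confounder testing, canonical correlation with the
clinical block, and the univariate group-comparison battery.

* :class:`RidgeCCA` / :func:`cca_first` — first canonical correlation between
  the discriminatory-VOC block and the lung-function block, both ln(1+x)
  transformed and column-standardized, with a ridge term on the within-block
  covariances for stability when columns are collinear or n is modest.
  Significance by permutation of the clinical rows (the test statistic's null
  is otherwise strongly biased upward: CCA maximizes correlation).
* :func:`cca_subset_select` — greedy forward selection over the clinical
  columns, scored by the permutation-corrected canonical correlation
  (observed rho1 minus the mean permuted rho1), so adding an uninformative
  column is penalized by exactly its expected overfit.
* :func:`rmanova_confounder` — regularized MANOVA: a shrinkage-Wilks
  statistic det(W + gI)/det(T + gI) usable when VOCs outnumber samples,
  shrinkage intensity from a Ledoit-Wolf-style rule on the pooled
  within-group covariance, p-value by permutation of the factor.
* :func:`univariate_table` — Welch t-tests per variable with
  Benjamini-Hochberg FDR correction and a Lilliefors normality flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.covariance import ledoit_wolf_shrinkage
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .io import ConfigurationError, ValidationError

logger = logging.getLogger("breathdisc")


# ---------------------------------------------------------------------------
# ridge-regularized CCA


def _prepare_block(M, name: str, log: bool = True) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if np.isnan(M).any():
        raise ValidationError(f"{name}: complete cases only (NaN present)")
    if log:
        # ln(1+x); columns with negative values are shifted to start at 0 first
        L = np.log1p(M - M.min(axis=0).clip(max=0))
    else:
        L = M
    sd = L.std(axis=0, ddof=1)
    const = sd <= 1e-12 * (np.abs(L.mean(axis=0)) + 1.0)
    if np.any(const):
        bad = list(np.flatnonzero(const))
        raise ValidationError(f"{name}: constant column(s) at index {bad}")
    return (L - L.mean(axis=0)) / sd


class RidgeCCA(BaseEstimator):
    """First canonical pair between two blocks with ridge-stabilized
    within-block covariances.

    Both blocks are ln(1+x)-transformed and column-standardized inside
    ``fit``. Fitted attributes: ``rho1_``, ``x_weights_``, ``y_weights_``,
    ``x_scores_``, ``y_scores_`` (unit-variance canonical variates).
    """

    def __init__(self, ridge: float = 1e-3, log: bool = True):
        self.ridge = ridge
        self.log = log

    def fit(self, X, Y):
        Xs = _prepare_block(X, "X", log=self.log)
        Ys = _prepare_block(Y, "Y", log=self.log)
        n = Xs.shape[0]
        if n != Ys.shape[0]:
            raise ValidationError("X and Y must have the same number of rows")
        if n <= max(Xs.shape[1], Ys.shape[1]):
            logger.warning(
                "CCA with n=%d <= block width; ridge %.1g is doing the stabilizing",
                n, self.ridge,
            )
        Sxx = Xs.T @ Xs / (n - 1) + self.ridge * np.eye(Xs.shape[1])
        Syy = Ys.T @ Ys / (n - 1) + self.ridge * np.eye(Ys.shape[1])
        Sxy = Xs.T @ Ys / (n - 1)
        # whiten both blocks, SVD of the cross-covariance
        Lx = sla.cholesky(Sxx, lower=True)
        Ly = sla.cholesky(Syy, lower=True)
        K = sla.solve_triangular(Lx, Sxy, lower=True)
        K = sla.solve_triangular(Ly, K.T, lower=True).T
        U, s, Vt = np.linalg.svd(K)
        a = sla.solve_triangular(Lx.T, U[:, 0], lower=False)
        b = sla.solve_triangular(Ly.T, Vt[0], lower=False)
        u, v = Xs @ a, Ys @ b
        u = u / u.std(ddof=1)
        v = v / v.std(ddof=1)
        rho = float(np.corrcoef(u, v)[0, 1])
        if rho < 0:  # sign convention: positive first correlation
            b, v, rho = -b, -v, -rho
        self.rho1_ = float(np.clip(rho, 0.0, 1.0))
        self.x_weights_, self.y_weights_ = a, b
        self.x_scores_, self.y_scores_ = u, v
        return self


@dataclass
class CcaResult:
    selected_columns: list
    x_weights: np.ndarray
    y_weights: np.ndarray
    rho1: float
    p_value: float | None
    x_variates: np.ndarray
    y_variates: np.ndarray


def cca_first(X, Y, ridge: float = 1e-3, column_names=None, log: bool = True) -> CcaResult:
    """First canonical correlation between a VOC block and a clinical block."""
    model = RidgeCCA(ridge=ridge, log=log).fit(X, Y)
    ncol = np.asarray(Y).shape[1] if np.asarray(Y).ndim > 1 else 1
    names = list(column_names) if column_names is not None else list(range(ncol))
    return CcaResult(
        selected_columns=names,
        x_weights=model.x_weights_,
        y_weights=model.y_weights_,
        rho1=model.rho1_,
        p_value=None,
        x_variates=model.x_scores_,
        y_variates=model.y_scores_,
    )


def cca_permutation_p(X, Y, B: int = 9999, ridge: float = 1e-3, seed: int = 0, log: bool = True) -> float:
    """p = (1 + #{rho1_perm >= rho1_obs}) / (B + 1), permuting the rows of Y."""
    if B < 1:
        raise ConfigurationError("B: must be >= 1")
    Y = np.asarray(Y, dtype=float)
    rho_obs = RidgeCCA(ridge=ridge, log=log).fit(X, Y).rho1_
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(Y.shape[0])
        if RidgeCCA(ridge=ridge, log=log).fit(X, Y[perm]).rho1_ >= rho_obs:
            count += 1
    return (1 + count) / (B + 1)


def cca_subset_select(
    X, Y_full, column_names, max_params: int | None = None,
    ridge: float = 1e-3, B_select: int = 499, B_final: int = 999,
    alpha: float = 0.05, seed: int = 0,
) -> CcaResult:
    """Greedy forward selection of clinical columns by permutation-corrected
    canonical correlation.

    At each step every remaining column is scored by rho1 of the augmented
    model minus its conditional-permutation mean (only the candidate column's
    rows are permuted; the accepted columns stay intact, so the penalty is
    exactly the overfit a useless extra column would buy). The best-scoring
    candidate is admitted if its conditional-permutation p-value clears a
    Bonferroni-corrected alpha (alpha / number of remaining candidates);
    otherwise selection stops. If no column is ever admitted the single
    highest-rho1 column is reported so the caller still gets a (then
    insignificant) model. The final model is refit on the selected columns
    with a fresh unconditional permutation p-value.
    """
    Y_full = np.asarray(Y_full, dtype=float)
    names = list(column_names)
    if Y_full.shape[1] != len(names):
        raise ValidationError("column_names must match Y_full's columns")
    max_params = max_params or len(names)
    rng = np.random.default_rng(seed)

    selected: list[int] = []
    remaining = list(range(len(names)))
    while remaining and len(selected) < max_params:
        best = None
        for j in remaining:
            Yj = Y_full[:, selected + [j]]
            rho = RidgeCCA(ridge=ridge).fit(X, Yj).rho1_
            r = np.random.default_rng(int(rng.integers(2**31)))
            perms = np.empty(B_select)
            for b in range(B_select):
                Yp = Yj.copy()
                Yp[:, -1] = Yp[r.permutation(Yp.shape[0]), -1]
                perms[b] = RidgeCCA(ridge=ridge).fit(X, Yp).rho1_
            score = rho - perms.mean()
            p_cond = (1 + int(np.sum(perms >= rho))) / (B_select + 1)
            if best is None or score > best[0] + 1e-12:
                best = (score, j, p_cond)
        score, j, p_cond = best
        if p_cond > alpha / len(remaining):
            break
        selected.append(j)
        remaining.remove(j)
        logger.info("CCA subset: added %s (corrected rho1 %.3f, conditional p %.4f)",
                    names[j], score, p_cond)

    if not selected:
        # degenerate: report the single best raw column with its p
        scores = [(RidgeCCA(ridge=ridge).fit(X, Y_full[:, [j]]).rho1_, -j)
                  for j in range(len(names))]
        selected = [-max(scores)[1]]
    result = cca_first(X, Y_full[:, selected], ridge=ridge,
                       column_names=[names[j] for j in selected])
    result.p_value = cca_permutation_p(
        X, Y_full[:, selected], B=B_final, ridge=ridge, seed=int(rng.integers(2**31))
    )
    return result


# ---------------------------------------------------------------------------
# regularized MANOVA confounder test


@dataclass
class ConfounderTestResult:
    factor: str
    comparison: str
    statistic: float      # shrinkage-Wilks ratio det(W+gI)/det(T+gI), small = effect
    gamma: float
    p_value: float
    n_levels: int


def rmanova_confounder(
    X, factor, B: int = 999, seed: int = 0,
    factor_name: str = "factor", comparison: str = "",
) -> ConfounderTestResult:
    """Does a study factor (age, sex, smoking...) structure the selected-VOC
    block? Shrinkage-Wilks statistic with a permutation p-value.

    Continuous factors are dichotomized at the median (logged). Statistic =
    det(W + gI) / det(T + gI), W/T the within/total scatter, g from a
    Ledoit-Wolf-style shrinkage rule on the pooled within-group covariance;
    smaller values mean more between-group separation.
    """
    X = np.asarray(X, dtype=float)
    factor = np.asarray(factor)
    if np.issubdtype(factor.dtype, np.number) and np.unique(factor).size > 2:
        med = np.median(factor.astype(float))
        logger.info("%s: continuous factor dichotomized at median %.3g", factor_name, med)
        factor = np.where(factor.astype(float) > med, "high", "low")
    levels = np.unique(factor)
    if levels.size < 2:
        raise ValidationError(f"{factor_name}: factor has a single level")

    Xc = X - X.mean(axis=0)
    p = X.shape[1]

    def wilks(labels):
        within = np.zeros((p, p))
        resid = np.empty_like(X)
        for lev in np.unique(labels):
            rows = labels == lev
            r = X[rows] - X[rows].mean(axis=0)
            within += r.T @ r
            resid[rows] = r
        total = Xc.T @ Xc
        shrink = ledoit_wolf_shrinkage(resid)
        mu = np.trace(within) / (p * max(X.shape[0] - len(np.unique(labels)), 1))
        g = shrink * mu * max(X.shape[0] - len(np.unique(labels)), 1)
        sW = np.linalg.slogdet(within + g * np.eye(p))[1]
        sT = np.linalg.slogdet(total + g * np.eye(p))[1]
        return float(np.exp(sW - sT)), g

    stat_obs, gamma = wilks(factor)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        s, _ = wilks(factor[rng.permutation(factor.size)])
        if s <= stat_obs:
            count += 1
    p_val = (1 + count) / (B + 1)
    return ConfounderTestResult(
        factor=factor_name, comparison=comparison, statistic=stat_obs,
        gamma=gamma, p_value=p_val, n_levels=int(levels.size),
    )


def confounder_report(fm_selected, clinical: pd.DataFrame, factors, comparisons,
                      B: int = 999, seed: int = 0) -> pd.DataFrame:
    """One permutation p per (factor, comparison) pair — the study-parameter
    influence table."""
    rows = []
    rng = np.random.default_rng(seed)
    for factor_name in factors:
        for comp in comparisons:
            mask = clinical["group"].isin(comp).to_numpy()
            vals = clinical.loc[mask, factor_name].to_numpy()
            res = rmanova_confounder(
                fm_selected[mask], vals, B=B, seed=int(rng.integers(2**31)),
                factor_name=factor_name, comparison=" vs ".join(comp),
            )
            rows.append({
                "factor": res.factor, "comparison": res.comparison,
                "statistic": res.statistic, "p_value": res.p_value,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# univariate battery (group characteristics table)


def univariate_table(df: pd.DataFrame, grouping, variables=None, welch: bool = True) -> pd.DataFrame:
    """Per-variable two-group comparison: t statistic, raw p, BH-adjusted p,
    and a Lilliefors normality pass flag per group.

    Zero-variance variables are flagged and excluded from the FDR battery.
    """
    grouping = np.asarray(grouping)
    levels = np.unique(grouping)
    if levels.size != 2:
        raise ValidationError(f"grouping must have exactly 2 levels, got {levels.size}")
    variables = variables or [c for c in df.columns if np.issubdtype(df[c].dtype, np.number)]
    rows = []
    for var in variables:
        a = df.loc[grouping == levels[0], var].dropna().to_numpy(dtype=float)
        b = df.loc[grouping == levels[1], var].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2 or (a.std(ddof=1) == 0 and b.std(ddof=1) == 0):
            rows.append({"variable": var, "t": np.nan, "p_raw": np.nan,
                         "normal_both": False, "excluded": True})
            continue
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
        normal = True
        for grp in (a, b):
            if grp.size >= 4:
                try:
                    _, lf_p = lilliefors(grp, dist="norm")
                    normal = normal and lf_p > 0.05
                except Exception:  # tiny degenerate samples
                    normal = False
        rows.append({"variable": var, "t": float(t), "p_raw": float(p),
                     "normal_both": bool(normal), "excluded": False})
    out = pd.DataFrame(rows)
    ok = ~out["excluded"]
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(out.loc[ok, "p_raw"], method="fdr_bh")[1]
    out["p_fdr"] = adj
    return out
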