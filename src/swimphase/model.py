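"""Association between micro-variables and goal metrics.

Workflow per goal metric: restrict the design matrix to the phases the
metric depends on, z-score the columns, iteratively remove multicollinear
columns by variance inflation factor (VIF), run LASSO variable selection
with a cross-validated penalty, convert coefficients to relative weights
(percent of the summed absolute standardized coefficients), keep variables
with at least 5% relative weight, sum weights per category, and finally
evaluate a LASSO regression of the goal metric on the selected variables
with leave-one-out cross-validation, reporting R², RMSE and relative RMSE.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV, lasso_path
from sklearn.model_selection import LeaveOneOut, cross_val_predict

from .features import category_of
from .types import CATEGORIES, RegressionReport, SelectionResult

log = logging.getLogger(__name__)

__all__ = [
    "normalize_features",
    "vif_filter",
    "lasso_select",
    "fit_evaluate_loocv",
    "assemble_design",
    "TARGET_PHASES",
]

ZERO_COEF = 1e-10


def normalize_features(X: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column (sample SD, ddof=1); constant columns are dropped."""
    if X.isna().any().any():
        raise ValueError("design matrix contains missing values")
    sd = X.std(ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} constant column(s): {list(constant)[:5]}...",
            RuntimeWarning,
        )
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    return (X - X.mean()) / sd


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 − R²_j) of column j regressed on the others."""
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        Xo = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Xo, yj, rcond=None)
        resid = yj - Xo @ beta
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(
    X: pd.DataFrame, threshold: float = 10.0
) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop the largest-VIF column until all VIF < threshold.

    Ties are broken by column order (first column wins removal).  With
    fewer than two columns the input passes through unchanged.
    """
    removed: list[str] = []
    X = X.copy()
    while X.shape[1] >= 2:
        vif = _vif_values(X.to_numpy())
        worst = int(np.argmax(vif))
        if vif[worst] < threshold:
            break
        removed.append(X.columns[worst])
        X = X.drop(columns=X.columns[worst])
    if removed:
        log.info("VIF filter removed %d column(s): %s", len(removed), removed)
    return X, removed


def _relative_weights(coef: np.ndarray, columns: pd.Index) -> dict[str, float]:
    a = np.abs(coef)
    a[a < ZERO_COEF] = 0.0
    total = a.sum()
    if total <= 0:
        return {}
    return {
        c: 100.0 * w / total for c, w in zip(columns, a) if w > 0
    }


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray,
    threshold_pct: float = 5.0,
    cv: int = 10,
    n_alphas: int = 100,
    seed: int = 0,
    penalty_rule: str = "1se",
) -> SelectionResult:
    """LASSO variable selection with relative weights and category sums.

    The penalty is chosen on a log-spaced grid by ``cv``-fold
    cross-validation.  For selection the default is the one-standard-error
    rule (the largest penalty whose CV error is within one standard error
    of the minimum): parsimony keeps spurious selections on pure-noise
    targets rare, at the price of slightly stronger shrinkage.
    ``penalty_rule='min'`` selects the CV-minimum instead.

    Relative weight of variable j is ``100·|β_j| / Σ|β|`` on the
    standardized design; variables below ``threshold_pct`` are neglected.
    Category contributions are the summed weights of the selected
    variables per category, reported both raw and renormalized to 100%.
    """
    if penalty_rule not in ("1se", "min"):
        raise ValueError("penalty_rule must be '1se' or 'min'")
    Xv = X.to_numpy()
    yc = np.asarray(y, dtype=float) - float(np.mean(y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        cvmod = LassoCV(alphas=n_alphas, cv=cv, random_state=seed, max_iter=5000)
        cvmod.fit(Xv, yc)
        alpha = float(cvmod.alpha_)
        if penalty_rule == "1se":
            mse = cvmod.mse_path_.mean(axis=1)
            se = cvmod.mse_path_.std(axis=1, ddof=1) / np.sqrt(cvmod.mse_path_.shape[1])
            i_min = int(np.argmin(mse))
            cutoff = mse[i_min] + se[i_min]
            # alphas_ are sorted descending: the first index within the cutoff
            # is the largest admissible penalty
            i_1se = int(np.argmax(mse <= cutoff))
            alpha = float(cvmod.alphas_[i_1se])
        fit = Lasso(alpha=alpha, max_iter=5000).fit(Xv, yc)
        coef = fit.coef_.copy()
        if np.all(np.abs(coef) < ZERO_COEF):
            # over-penalized: fall back to the smallest penalty with support
            warnings.warn(
                "cross-validated penalty selects no variables; "
                "falling back to the largest penalty with at least one",
                RuntimeWarning,
            )
            alphas, coefs, _ = lasso_path(Xv, yc, alphas=n_alphas)
            nnz = (np.abs(coefs) > ZERO_COEF).sum(axis=0)
            ok = np.flatnonzero(nnz >= 1)
            if len(ok) == 0:
                raise ValueError("LASSO path never activates a variable")
            alpha = float(alphas[ok[0]])
            coef = coefs[:, ok[0]].copy()

    weights = _relative_weights(coef, X.columns)
    selected = [c for c, w in weights.items() if w >= threshold_pct]
    selected.sort(key=lambda c: -weights[c])
    contrib = {cat: 0.0 for cat in CATEGORIES}
    for c in selected:
        contrib[_safe_category(c)] += weights[c]
    total_sel = sum(contrib.values())
    renorm = {
        cat: (100.0 * v / total_sel if total_sel > 0 else 0.0)
        for cat, v in contrib.items()
    }
    return SelectionResult(
        weights=weights,
        selected=selected,
        category_contrib=contrib,
        category_contrib_renorm=renorm,
        alpha=alpha,
        threshold_pct=threshold_pct,
    )


def _safe_category(name: str) -> str:
    try:
        return category_of(name)
    except KeyError:
        return "duration_rate"


def fit_evaluate_loocv(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    alpha: float | None = None,
    cv: int = 10,
    seed: int = 0,
) -> RegressionReport:
    """Leave-one-out cross-validated LASSO regression report.

    Each observation is predicted by a model refit on all others; R² is
    computed on the pooled held-out predictions, RMSE is the root mean
    squared held-out error and the relative RMSE is RMSE as a percent of
    the target mean.  If ``alpha`` is not given it is chosen once by
    ``cv``-fold cross-validation on the full data.
    """
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 observations for LOO evaluation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if alpha is None:
            cvmod = LassoCV(alphas=100, cv=cv, random_state=seed, max_iter=5000)
            cvmod.fit(Xv, y)
            alpha = float(cvmod.alpha_)
        pred = cross_val_predict(Lasso(alpha=alpha, max_iter=5000), Xv, y, cv=LeaveOneOut())
    resid = y - pred
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    rmse = float(np.sqrt(np.mean(resid**2)))
    mean_y = float(np.mean(y))
    if mean_y == 0.0:
        warnings.warn("target mean is zero; relative RMSE undefined", RuntimeWarning)
        rel = float("nan")
    else:
        rel = 100.0 * rmse / abs(mean_y)
    return RegressionReport(target="", r2=r2, rmse=rmse, rel_rmse=rel, n_obs=n)


#: phases whose micro-variables enter each goal metric's design matrix
TARGET_PHASES = {
    "push_vmax": ("Push",),
    "glid_vend": ("Glid",),
    "stpr_vavg": ("StPr",),
    "swim_vavg_cycle": ("Cycle",),
    "swim_vavg_phase": ("Swim",),
    "T5m": ("Push", "Glid"),
    "T15m": ("Push", "Glid", "StPr"),
    "lap_vavg": ("Push", "Glid", "StPr", "Swim"),
}


def assemble_design(
    features: pd.DataFrame, target: str, goals: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray]:
    """Scope the feature table to the phases relevant for ``target``.

    ``features`` holds lap rows (or cycle rows for the per-cycle target)
    indexed like ``goals``; metadata columns (non-catalogue names) are
    ignored.  Returns the scoped X and the target vector y.
    """
    if target not in TARGET_PHASES:
        raise ValueError(f"unknown goal metric {target!r}")
    prefixes = tuple(p + "." for p in TARGET_PHASES[target])
    cols = [c for c in features.columns if c.startswith(prefixes)]
    if not cols:
        raise ValueError(f"no feature columns for target {target!r}")
    if target not in goals.columns:
        raise ValueError(f"goals table lacks column {target!r}")
    joined = features[cols].join(goals[[target]], how="inner")
    y = joined.pop(target).to_numpy(dtype=float)
    return joined, y
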