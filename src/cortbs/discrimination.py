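"""Fracture-discrimination statistics: SPA variable selection, PLS-LDA with
leave-one-out cross-validation, standardized risk scores, ROC analysis with
the Hanley-McNeil correlated-AUC test, and PLS regression of aBMD.

Class coding is Fx = 1, nFx = 0 throughout.  The PLS-LDA predictor is the
continuous PLS-regression output on the 0/1 labels; leave-one-out
cross-validated predictors feed the ROC, and risk scores are the predictors
standardized against the non-fractured control reference (oriented so that
lower score means higher risk, matching the T-score convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import floor, sqrt

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from . import reference_cohort as ref
from .errors import InputError

__all__ = [
    "spa_select_variables", "fit_pls_lda_loocv", "compute_risk_score",
    "roc_analysis", "hanley_mcneil_se", "hanley_mcneil_compare",
    "pls_regression_cv", "discriminate", "SPAResult", "DiscriminationResult",
    "ROCResult", "RegressionResult", "FEATURE_SETS",
]

FEATURE_SETS = {
    "cortbs": list(ref.CORTBS_PARAMS),
    "dxa": list(ref.DXA_PARAMS),
    "cortbs+ap": list(ref.CORTBS_PARAMS) + list(ref.ANTHRO_PARAMS),
    "dxa+ap": list(ref.DXA_PARAMS) + list(ref.ANTHRO_PARAMS),
}


# --- results --------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    auc_se: float
    sensitivity: float
    specificity: float
    accuracy: float
    threshold: float


@dataclass
class SPAResult:
    selected: list[str]
    importance: dict[str, float]
    p_values: dict[str, float]
    stable: bool
    n_repeats: int


@dataclass
class DiscriminationResult:
    selected_variables: list[str]
    n_components: int
    loocv_scores: np.ndarray
    model_coefficients: dict[str, float]
    risk_scores: np.ndarray | None = None
    roc: ROCResult | None = None


@dataclass
class RegressionResult:
    predictions: np.ndarray
    spearman_rho: float
    rmse: float
    fold_assignment: np.ndarray = field(default=None, repr=False)


# --- PLS core -------------------------------------------------------------

def _as_matrix(X, columns=None):
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns) if columns is None else list(columns)
        return X[cols].to_numpy(dtype=float), cols
    X = np.asarray(X, dtype=float)
    cols = [f"x{i}" for i in range(X.shape[1])] if columns is None else list(columns)
    return X, cols


def _standardize_train(Xtr):
    mean = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    keep = sd > 0
    return mean, sd, keep


def _pls_fit(Xtr, ytr, cap, rel_tol=1e-3):
    """Fit PLS on the training data; choose the smallest component count
    whose fitted-response RMSE is within ``rel_tol`` (relative) of the
    minimum over 1..cap.  Returns (coefficients, intercept-like means, k)."""
    cap = int(min(cap, Xtr.shape[1], Xtr.shape[0] - 1))
    cap = max(cap, 1)
    pls = PLSRegression(n_components=cap, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Xtr, ytr)
    k_avail = pls.x_scores_.shape[1]
    # cumulative fitted responses over components (NIPALS structure Y ~ T Q')
    contrib = pls.x_scores_ * pls.y_loadings_[0]  # (n, K)
    fitted = np.cumsum(contrib, axis=1) + ytr.mean()
    rmse = np.sqrt(np.mean((fitted - ytr[:, None]) ** 2, axis=0))
    best = rmse.min()
    k = int(np.argmax(rmse <= best * (1 + rel_tol) + 1e-15)) + 1
    coef = pls.x_rotations_[:, :k] @ pls.y_loadings_[:, :k].T  # (p, 1)
    return coef[:, 0], Xtr.mean(axis=0), float(ytr.mean()), min(k, k_avail)


def _pls_predict(Xte, coef, x_mean, y_mean):
    return (Xte - x_mean) @ coef + y_mean


def fit_pls_lda_loocv(
    X,
    y,
    selected: list[str] | None = None,
    component_cap: int | None = None,
) -> DiscriminationResult:
    """Leave-one-out cross-validated PLS-LDA predictor.

    For each subject a PLS model (components chosen per fold by the
    fitted-response criterion, capped at ``component_cap``, default
    ``floor(n/10)``) is fitted on the remaining subjects after per-fold
    standardization, and emits a continuous predictor for the held-out
    subject.  Deterministic given its inputs and invariant to subject
    ordering (up to the same permutation of the scores).
    """
    Xm, cols = _as_matrix(X, selected)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise InputError("need at least 10 subjects for PLS-LDA LOOCV")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise InputError("labels must be binary 0/1")
    cap = floor(n / 10) if component_cap is None else int(component_cap)
    if cap < 1:
        raise InputError("component cap must be >= 1")

    scores = np.empty(n)
    k_used = 0
    dropped_any = False
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = Xm[mask], y[mask]
        mean, sd, keep = _standardize_train(Xtr)
        if not keep.all():
            dropped_any = True
        Xtr_s = (Xtr[:, keep] - mean[keep]) / sd[keep]
        coef, x_mean, y_mean, k = _pls_fit(Xtr_s, ytr, cap)
        k_used = max(k_used, k)
        Xte_s = (Xm[i, keep] - mean[keep]) / sd[keep]
        scores[i] = _pls_predict(Xte_s, coef, x_mean, y_mean)
    if dropped_any:
        warnings.warn("constant columns were dropped in some folds", stacklevel=2)

    # full-data model for the reported coefficients
    mean, sd, keep = _standardize_train(Xm)
    Xs = (Xm[:, keep] - mean[keep]) / sd[keep]
    coef, *_ , k_full = _pls_fit(Xs, y, cap)
    kept_cols = [c for c, k in zip(cols, keep) if k]
    return DiscriminationResult(
        selected_variables=cols,
        n_components=max(k_used, k_full),
        loocv_scores=scores,
        model_coefficients=dict(zip(kept_cols, coef)),
    )


# --- risk scores ----------------------------------------------------------

def compute_risk_score(
    loocv_scores,
    reference_mask,
    orientation: float = 1.0,
) -> np.ndarray:
    """Standardize predictor values against a reference sub-population.

    ``score_i = orientation * (s_i - mean_ref) / sd_ref``; the reference
    (non-fractured controls) has mean 0 and SD 1 by construction.  Pass
    ``orientation=-1`` when the raw predictor increases with risk, so that
    lower risk scores mean higher risk (the T-score convention).
    """
    s = np.asarray(loocv_scores, dtype=float)
    mask = np.asarray(reference_mask, dtype=bool)
    if mask.sum() == 0:
        raise InputError("reference population is empty")
    sd = s[mask].std(ddof=1)
    if sd == 0:
        raise InputError("reference population has zero score variance")
    return orientation * (s - s[mask].mean()) / sd


# --- ROC ------------------------------------------------------------------

def roc_analysis(scores, labels) -> ROCResult:
    """Rank (Mann-Whitney) AUC with Hanley-McNeil SE and the Youden point.

    Ties count half; the operating point maximizes sensitivity +
    specificity - 1, with sensitivity/specificity/accuracy reported there.
    Higher scores are assumed to indicate the positive class.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("both classes must be present for ROC analysis")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    se = hanley_mcneil_se(auc, n_pos, n_neg)

    # Youden-optimal threshold: cumulative counts over descending scores
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    sens_all = np.r_[0.0, tps[distinct] / n_pos]
    spec_all = np.r_[1.0, 1.0 - fps[distinct] / n_neg]
    youden = sens_all + spec_all - 1.0
    k = int(np.argmax(youden))
    cut = np.r_[s_sorted[distinct], -np.inf]
    best_t = float(s_sorted[0] + 1.0) if k == 0 else float(
        (cut[k - 1] + cut[k]) / 2.0 if np.isfinite(cut[k])
        else cut[k - 1] - 1.0)
    best_sens, best_spec = float(sens_all[k]), float(spec_all[k])
    pred = s > best_t
    acc = float(np.mean(pred == (y == 1)))
    return ROCResult(auc=float(auc), auc_se=float(se),
                     sensitivity=float(best_sens), specificity=float(best_spec),
                     accuracy=acc, threshold=float(best_t))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Closed-form standard error of the rank AUC (Hanley & McNeil, 1982)."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    return sqrt(max(var, 0.0))


def hanley_mcneil_compare(scores_a, scores_b, labels) -> tuple[float, float]:
    """Correlated-AUC z-test for two score sets on the same subjects.

    ``z = (AUC_A - AUC_B) / sqrt(SE_A^2 + SE_B^2 - 2 r SE_A SE_B)`` with
    ``r`` the average of the between-score Pearson correlations within each
    class (the standard stand-in for the tabulated correlation).  Returns
    ``(z, two-sided p)``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise InputError("score vectors and labels must have matching lengths")
    roc_a = roc_analysis(a, y)
    roc_b = roc_analysis(b, y)

    def safe_corr(u, v):
        if np.std(u) == 0 or np.std(v) == 0:
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    r = 0.5 * (safe_corr(a[y == 1], b[y == 1]) + safe_corr(a[y == 0], b[y == 0]))
    var = roc_a.auc_se**2 + roc_b.auc_se**2 - 2 * r * roc_a.auc_se * roc_b.auc_se
    diff = roc_a.auc - roc_b.auc
    if var <= 0:
        return (0.0, 1.0) if abs(diff) < 1e-12 else (np.sign(diff) * np.inf, 0.0)
    z = diff / sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


# --- SPA variable selection ----------------------------------------------

def spa_select_variables(
    X,
    y,
    n_mc: int = 2000,
    rng_seed: int = 0,
    *,
    alpha: float = 0.05,
    train_fraction: float = 0.8,
    window_fraction: float = 0.5,
    max_repeats: int = 10,
    n_components: int = 2,
) -> SPAResult:
    """Sub-window permutation analysis for variable selection.

    Each Monte-Carlo sampling draws a random subject subset and a random
    variable sub-window, fits a PLS-LDA sub-model, and records the held-out
    misclassification error twice per included variable: with the variable
    intact and with its held-out values permuted.  A variable is selected
    when its permuted errors are stochastically larger than its normal
    errors (one-sided rank test, ``p < alpha``).  The whole analysis is
    repeated until the selected set is identical on two consecutive
    repetitions (at most ``max_repeats``); a non-stable final set is
    flagged.
    """
    Xm, cols = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n_mc < 100:
        raise InputError("n_mc must be >= 100")
    if p < 2:
        raise InputError("need at least 2 variables")
    classes = np.unique(y)
    if len(classes) < 2:
        raise InputError("both classes must be present")

    rng = np.random.default_rng(rng_seed)
    q = max(2, int(round(p * window_fraction)))
    n_tr = max(4, int(round(n * train_fraction)))

    def one_repetition():
        normal_err = [[] for _ in range(p)]
        permuted_err = [[] for _ in range(p)]
        for _ in range(n_mc):
            while True:
                tr = rng.choice(n, size=n_tr, replace=False)
                te = np.setdiff1d(np.arange(n), tr)
                if len(np.unique(y[tr])) == 2 and te.size:
                    break
            sub = rng.choice(p, size=q, replace=False)
            Xtr = Xm[np.ix_(tr, sub)]
            mean, sd, keep = _standardize_train(Xtr)
            if keep.sum() == 0:
                continue
            Xtr_s = (Xtr[:, keep] - mean[keep]) / sd[keep]
            coef, x_mean, y_mean, _ = _pls_fit(
                Xtr_s, y[tr], min(n_components, max(1, floor(n_tr / 10))))
            Xte = Xm[np.ix_(te, sub)][:, keep]
            Xte_s = (Xte - mean[keep]) / sd[keep]
            pred = _pls_predict(Xte_s, coef, x_mean, y_mean)
            err0 = float(np.mean((pred > 0.5) != (y[te] == 1)))
            kept_vars = sub[keep]
            for j, var in enumerate(kept_vars):
                perm = rng.permutation(Xte_s.shape[0])
                Xp = Xte_s.copy()
                Xp[:, j] = Xp[perm, j]
                pred_p = _pls_predict(Xp, coef, x_mean, y_mean)
                err1 = float(np.mean((pred_p > 0.5) != (y[te] == 1)))
                normal_err[var].append(err0)
                permuted_err[var].append(err1)
        p_vals, importance = {}, {}
        selected = []
        for v in range(p):
            ne, pe = np.asarray(normal_err[v]), np.asarray(permuted_err[v])
            if ne.size < 10:
                p_vals[cols[v]] = 1.0
                importance[cols[v]] = 0.0
                continue
            importance[cols[v]] = float(pe.mean() - ne.mean())
            if np.all(pe == ne):
                p_vals[cols[v]] = 1.0
            else:
                p_vals[cols[v]] = float(
                    stats.mannwhitneyu(pe, ne, alternative="greater",
                                       method="asymptotic").pvalue)
            if p_vals[cols[v]] < alpha:
                selected.append(cols[v])
        return selected, importance, p_vals

    prev = None
    stable = False
    for rep in range(1, max_repeats + 1):
        selected, importance, p_vals = one_repetition()
        if prev is not None and set(selected) == set(prev):
            stable = True
            break
        prev = selected
    return SPAResult(selected=selected, importance=importance,
                     p_values=p_vals, stable=stable, n_repeats=rep)


# --- PLS regression of aBMD -----------------------------------------------

def pls_regression_cv(
    X,
    y,
    k: int = 3,
    rng_seed: int = 0,
    component_cap: int | None = None,
) -> RegressionResult:
    """k-fold cross-validated PLS regression with Spearman rho and RMSE.

    Out-of-fold predictions are assembled over seeded, shuffled folds;
    ``rho`` and ``rmse`` compare them with the observed response.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3 * k:
        raise InputError(f"need at least {3 * k} observations for {k}-fold CV")
    if np.std(y) == 0:
        raise InputError("constant response")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(n)
    folds = np.zeros(n, dtype=int)
    for f, part in enumerate(np.array_split(order, k)):
        folds[part] = f
    preds = np.empty(n)
    for f in range(k):
        te = folds == f
        tr = ~te
        mean, sd, keep = _standardize_train(Xm[tr])
        Xtr_s = (Xm[tr][:, keep] - mean[keep]) / sd[keep]
        cap = component_cap if component_cap is not None else floor(tr.sum() / 10)
        coef, x_mean, y_mean, _ = _pls_fit(Xtr_s, y[tr], max(1, cap))
        Xte_s = (Xm[te][:, keep] - mean[keep]) / sd[keep]
        preds[te] = _pls_predict(Xte_s, coef, x_mean, y_mean)
    rho = stats.spearmanr(preds, y).statistic
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    return RegressionResult(predictions=preds, spearman_rho=float(rho),
                            rmse=rmse, fold_assignment=folds)


# --- high-level driver ----------------------------------------------------

def discriminate(
    cohort: pd.DataFrame,
    outcome: str = "any",
    features: str = "cortbs",
    *,
    use_spa: bool = False,
    n_mc: int = 2000,
    rng_seed: int = 0,
) -> DiscriminationResult:
    """Run the full discrimination analysis on a cohort table.

    ``outcome`` selects the fracture label (``vertebral``, ``other`` or
    ``any``); ``features`` a named variable set (:data:`FEATURE_SETS`).
    Optionally SPA-selects variables first, then fits the LOOCV predictor,
    standardizes risk scores against non-fractured controls (oriented so
    fracture groups score lower) and attaches the ROC summary.
    """
    if features not in FEATURE_SETS:
        raise InputError(f"unknown feature set {features!r}; "
                         f"choose from {sorted(FEATURE_SETS)}")
    label_col = f"fracture_{outcome}"
    if label_col not in cohort.columns:
        raise InputError(f"cohort has no column {label_col!r}")
    cols = FEATURE_SETS[features]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise InputError(f"cohort is missing feature columns: {missing}")
    y = cohort[label_col].astype(bool).to_numpy().astype(float)
    X = cohort[cols]
    selected = cols
    if use_spa:
        spa = spa_select_variables(X, y, n_mc=n_mc, rng_seed=rng_seed)
        if len(spa.selected) >= 1:
            selected = spa.selected if len(spa.selected) >= 2 else spa.selected
        if len(selected) < 2:  # fall back to the full set on degenerate selection
            selected = cols
    result = fit_pls_lda_loocv(cohort[selected], y, selected=selected)
    reference = (cohort["group"] == "control") & ~cohort["fracture_any"].astype(bool)
    result.risk_scores = compute_risk_score(result.loocv_scores,
                                            reference.to_numpy(),
                                            orientation=-1.0)
    result.roc = roc_analysis(result.loocv_scores, y)
    return result
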