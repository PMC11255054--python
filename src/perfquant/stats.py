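"""Group comparison statistics for two-class perfusion feature tables.

Implements the univariate stage of the analysis: Mann-Whitney U tests,
per-feature AUC-ROC under tenfold stratified cross-validation, paired AUC
comparison (DeLong Z-test), Bonferroni correction, Spearman correlation and
Youden-optimal operating thresholds.  The positive class throughout is the
oligodendroglioma (higher nrCBV, lower PSR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import ParameterError, StratificationError

POSITIVE_LABEL = "oligodendroglioma"
DEFAULT_BONFERRONI_M = 44  # 2 metrics x 22 summary values


def binarize_labels(labels, positive_label: str = POSITIVE_LABEL) -> np.ndarray:
    y = np.asarray([1 if lab == positive_label else 0 for lab in labels])
    if y.min() == y.max():
        raise ParameterError("both classes must be present")
    return y


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Small untied samples use the exact null distribution; otherwise the
    normal approximation with tie and continuity corrections is applied
    (scipy's ``method="auto"`` policy).  The returned U statistic is the one
    for group ``a``.  Each group should have at least 3 observations.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CvAucResult:
    """Cross-validated single-feature AUC: mean/SD over held-out folds."""

    auc_mean: float
    auc_sd: float
    ci95: tuple[float, float]
    fold_aucs: tuple[float, ...]
    pooled_auc: float


def cv_feature_auc(values, labels, k: int = 10, seed: int = 0) -> CvAucResult:
    """AUC-ROC of one feature under stratified k-fold cross-validation.

    Per fold, the feature's orientation (sign as a score) is chosen on the
    training portion (flipped if the training AUC < 0.5) and the AUC is
    computed on the held-out portion.  The CI is mean ± 1.96·SD/√k clipped
    to [0, 1].  A pooled AUC over the oriented out-of-fold scores is also
    reported.
    """
    x = np.asarray(values, float)
    y = binarize_labels(labels) if not np.issubdtype(
        np.asarray(labels).dtype, np.number
    ) else np.asarray(labels, int)
    if min(np.bincount(y, minlength=2)) < k:
        raise StratificationError(
            f"need >= {k} subjects per class for {k}-fold stratification"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs = []
    pooled_scores = np.empty_like(x)
    for train, test in skf.split(x.reshape(-1, 1), y):
        if y[test].min() == y[test].max() or y[train].min() == y[train].max():
            raise StratificationError("a fold lacks one of the classes")
        sign = 1.0 if roc_auc_score(y[train], x[train]) >= 0.5 else -1.0
        fold_aucs.append(roc_auc_score(y[test], sign * x[test]))
        pooled_scores[test] = sign * x[test]
    fold_aucs = np.asarray(fold_aucs)
    mean, sd = float(fold_aucs.mean()), float(fold_aucs.std(ddof=1))
    half = 1.96 * sd / np.sqrt(k)
    ci = (max(0.0, mean - half), min(1.0, mean + half))
    return CvAucResult(
        auc_mean=mean, auc_sd=sd, ci95=ci,
        fold_aucs=tuple(float(a) for a in fold_aucs),
        pooled_auc=float(roc_auc_score(y, pooled_scores)),
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_auc_cov(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their covariance matrix for paired predictors (DeLong).

    ``scores`` has one row per predictor; higher score must indicate the
    positive class.  Uses the midrank formulation.
    """
    pos = scores[:, y == 1]
    neg = scores[:, y == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = scores.shape[0]
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.concatenate([pos[r], neg[r]]))
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    return aucs, np.atleast_2d(s10) / m + np.atleast_2d(s01) / n


def compare_auc(values1, values2, labels) -> tuple[float, float]:
    """DeLong Z-test comparing the AUCs of two paired features.

    Each feature is first oriented so its AUC is >= 0.5 (the metrics run in
    opposite directions across tumor types).  Returns (z, two-sided p).
    """
    x1, x2 = np.asarray(values1, float), np.asarray(values2, float)
    if x1.size != x2.size:
        raise ParameterError("features must be measured on the same subjects")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise ParameterError("degenerate (constant) feature")
    y = binarize_labels(labels) if not np.issubdtype(
        np.asarray(labels).dtype, np.number
    ) else np.asarray(labels, int)
    s1 = x1 if roc_auc_score(y, x1) >= 0.5 else -x1
    s2 = x2 if roc_auc_score(y, x2) >= 0.5 else -x2
    aucs, cov = _delong_auc_cov(np.vstack([s1, s2]), y)
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 0:
        return 0.0, 1.0
    z = float((aucs[0] - aucs[1]) / np.sqrt(var_diff))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return z, p


def bonferroni(p_values, m: int = DEFAULT_BONFERRONI_M) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, m·p) for a family of size m."""
    p = np.asarray(p_values, float)
    if m < p.size:
        raise ParameterError(f"family size m={m} smaller than {p.size} tests")
    return np.minimum(1.0, m * p)


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p over the columns of a feature table.

    Rank correlation with average ranks for ties; p by the t approximation.
    Constant columns yield NaN (rho undefined).
    """
    if len(table) < 5:
        raise ParameterError("need at least 5 subjects")
    cols = list(table.columns)
    n = len(cols)
    rho = np.full((n, n), np.nan)
    pv = np.full((n, n), np.nan)
    for i in range(n):
        xi = table[cols[i]].to_numpy(float)
        for j in range(i, n):
            xj = table[cols[j]].to_numpy(float)
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue
            if i == j:
                rho[i, j], pv[i, j] = 1.0, 0.0
                continue
            r, p = sps.spearmanr(xi, xj)
            rho[i, j] = rho[j, i] = r
            pv[i, j] = pv[j, i] = p
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pv, index=cols, columns=cols),
    )


@dataclass(frozen=True)
class YoudenResult:
    """Youden-optimal operating point of one feature.

    ``direction`` is +1 when values above the threshold call the positive
    class, −1 when values below do.
    """

    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    direction: int


def youden_threshold(values, labels) -> YoudenResult:
    """Threshold maximizing Youden's J = sensitivity + specificity − 1.

    Candidate thresholds are the midpoints between consecutive sorted unique
    values; both orientations are scanned so that J >= 0; ties are broken
    toward higher specificity.  Sensitivity is defined on the positive
    (oligodendroglioma) class.
    """
    x = np.asarray(values, float)
    y = binarize_labels(labels) if not np.issubdtype(
        np.asarray(labels).dtype, np.number
    ) else np.asarray(labels, int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("both classes must be present")
    uniq = np.unique(x)
    if uniq.size == 1:
        return YoudenResult(float(uniq[0]), 0.0, 1.0, n_neg / y.size, +1)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for direction in (+1, -1):
        for thr in cands:
            pred = (x > thr) if direction == +1 else (x < thr)
            sens = float((pred & (y == 1)).sum() / n_pos)
            spec = float((~pred & (y == 0)).sum() / n_neg)
            j = sens + spec - 1.0
            key = (round(j, 12), round(spec, 12))
            if best is None or key > best[0]:
                acc = float((pred == (y == 1)).mean())
                best = (key, YoudenResult(float(thr), sens, spec, acc, direction))
    return best[1]


def feature_stat_table(
    cohort: pd.DataFrame,
    feature_columns,
    label_column: str = "label",
    k: int = 10,
    seed: int = 0,
    bonferroni_m: int = DEFAULT_BONFERRONI_M,
    positive_label: str = POSITIVE_LABEL,
) -> pd.DataFrame:
    """One statistics row per feature over a two-class cohort table.

    Columns: per-class mean/SD, Mann-Whitney U and raw/Bonferroni p,
    cross-validated AUC (mean, SD, CI), pooled AUC, and the Youden-optimal
    threshold with its sensitivity/specificity/accuracy.
    """
    y = binarize_labels(cohort[label_column], positive_label)
    rows = []
    for feat in feature_columns:
        x = cohort[feat].to_numpy(float)
        a, b = x[y == 1], x[y == 0]
        u, p = mann_whitney(a, b)
        auc = cv_feature_auc(x, y, k=k, seed=seed)
        yt = youden_threshold(x, y)
        rows.append({
            "feature": feat,
            "mean_pos": a.mean(), "sd_pos": a.std(ddof=1),
            "mean_neg": b.mean(), "sd_neg": b.std(ddof=1),
            "u_stat": u, "p_raw": p,
            "auc_mean": auc.auc_mean, "auc_sd": auc.auc_sd,
            "auc_ci_lo": auc.ci95[0], "auc_ci_hi": auc.ci95[1],
            "pooled_auc": auc.pooled_auc,
            "youden_threshold": yt.threshold,
            "sensitivity": yt.sensitivity, "specificity": yt.specificity,
            "accuracy": yt.accuracy, "direction": yt.direction,
        })
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out.p_raw.to_numpy(), m=bonferroni_m)
    return out
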