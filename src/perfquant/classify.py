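"""Combined-metric classification of tumor type from percentile features.

The stage mirrors the univariate-filter → recursive-feature-elimination →
gradient-boosting design: features passing a strict univariate screen
(cross-validated AUC > 0.8 and Mann-Whitney p < 0.005 by default) are pruned
by backward elimination to the five that maximize cross-validated accuracy,
then a gradient-boosted tree classifier is evaluated with tenfold stratified
cross-validation and refit on the full cohort for prospective use.

The whole stage is exposed as the scikit-learn compatible estimator
:class:`AucFilteredBoostingClassifier`; the module-level functions
(:func:`filter_candidates`, :func:`rfe_top5`, :func:`train_eval_gbm`,
:func:`predict_case`) are thin wrappers kept for pipeline scripting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.utils.validation import check_is_fitted

from . import stats as gstats
from .errors import EmptyCandidateSet, ParameterError, StratificationError

POSITIVE_LABEL = gstats.POSITIVE_LABEL

DEFAULT_GBM_PARAMS = dict(
    n_estimators=100, max_depth=3, learning_rate=0.1, subsample=1.0
)


@dataclass
class ClassifierReport:
    """Audit record of one cross-validated classification run."""

    candidates: pd.DataFrame  # feature, auc_mean, p_raw of the post-filter set
    selected_features: list[str]  # in descending importance order
    importances: dict[str, float]  # normalized to sum 1
    fold_aucs: list[float]
    auc_mean: float
    auc_sd: float
    auc_ci95: tuple[float, float]
    pooled_auc: float
    best_fold_auc: float
    seed: int
    hyperparameters: dict = field(default_factory=dict)
    rfe_passthrough: bool = False

    def to_dict(self) -> dict:
        return {
            "candidates": self.candidates.to_dict(orient="records"),
            "selected_features": list(self.selected_features),
            "importances": dict(self.importances),
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "auc_ci95": list(self.auc_ci95),
            "pooled_auc": self.pooled_auc,
            "best_fold_auc": self.best_fold_auc,
            "seed": self.seed,
            "hyperparameters": dict(self.hyperparameters),
            "rfe_passthrough": self.rfe_passthrough,
        }


def _check_stratifiable(y: np.ndarray, k: int) -> None:
    if min(np.bincount(y, minlength=2)) < k:
        raise StratificationError(f"need >= {k} subjects per class for {k} folds")


def filter_candidates(
    stat_rows: pd.DataFrame, auc_min: float = 0.8, p_max: float = 0.005
) -> list[str]:
    """Features with cross-validated AUC strictly above ``auc_min`` and raw
    Mann-Whitney p strictly below ``p_max``.

    Raises :class:`EmptyCandidateSet` when nothing survives (the combined
    classifier is then not attempted).
    """
    keep = stat_rows[(stat_rows.auc_mean > auc_min) & (stat_rows.p_raw < p_max)]
    if keep.empty:
        raise EmptyCandidateSet(
            f"no feature with AUC > {auc_min} and p < {p_max}"
        )
    return list(keep.feature)


def _gbm(seed: int, hyper: dict) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(random_state=seed, **hyper)


def rfe_top5(
    table: pd.DataFrame,
    candidates: list[str],
    seed: int = 0,
    n_keep: int = 5,
    inner_folds: int = 5,
    label_column: str = "label",
    positive_label: str = POSITIVE_LABEL,
    hyperparameters: dict | None = None,
) -> tuple[list[str], bool]:
    """Backward feature elimination to ``n_keep`` features.

    At each step every candidate removal is scored by mean stratified
    ``inner_folds``-fold cross-validated accuracy of the boosted classifier.
    Because CV accuracy differences between removals are often within
    estimation noise, a one-standard-error rule decides: among removals
    whose accuracy lies within one SE of the best, the feature with the
    lowest fold-averaged impurity importance (in the model trained on the
    full current set) is dropped — accuracy stays the primary criterion,
    importance resolves statistical ties.  Deterministic given the seed and
    invariant to column order.  With fewer than ``n_keep`` candidates all
    are returned and the pass-through flag is set.
    """
    hyper = dict(DEFAULT_GBM_PARAMS, **(hyperparameters or {}))
    y = gstats.binarize_labels(table[label_column], positive_label)
    current = sorted(candidates)  # canonical order: column-permutation invariant
    if len(current) < n_keep:
        warnings.warn(
            f"only {len(current)} candidates (< {n_keep}); passing all through",
            stacklevel=2,
        )
        return current, True
    _check_stratifiable(y, inner_folds)
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    while len(current) > n_keep:
        X_full = table[current].to_numpy(float)
        fold_imps = []
        for train, _ in skf.split(X_full, y):
            fold_imps.append(
                _gbm(seed, hyper).fit(X_full[train], y[train]).feature_importances_
            )
        importance = dict(zip(current, np.mean(fold_imps, axis=0)))
        scores = {}
        for drop in current:
            trial = [f for f in current if f != drop]
            accs = cross_val_score(
                _gbm(seed, hyper), table[trial].to_numpy(), y, cv=skf,
                scoring="accuracy",
            )
            scores[drop] = (accs.mean(), accs.std(ddof=1) / np.sqrt(len(accs)))
        best_acc, best_se = max(scores.values(), key=lambda t: t[0])
        in_band = [f for f in current if scores[f][0] >= best_acc - best_se - 1e-12]
        best_drop = min(in_band, key=lambda f: (importance[f], f))
        current = [f for f in current if f != best_drop]
    return current, False


def train_eval_gbm(
    table: pd.DataFrame,
    features: list[str],
    k: int = 10,
    seed: int = 0,
    label_column: str = "label",
    positive_label: str = POSITIVE_LABEL,
    hyperparameters: dict | None = None,
    candidates: pd.DataFrame | None = None,
) -> tuple[ClassifierReport, dict]:
    """Cross-validate and refit the gradient-boosted classifier.

    Per stratified fold, the model is fit on the training rows and scored on
    the held-out rows (AUC-ROC).  Impurity importances are averaged over the
    fold models and normalized to sum 1.  The returned bundle contains the
    model refit on all rows plus everything needed to score a new case.
    """
    features = sorted(features)
    hyper = dict(DEFAULT_GBM_PARAMS, **(hyperparameters or {}))
    y = gstats.binarize_labels(table[label_column], positive_label)
    _check_stratifiable(y, k)
    X = table[features].to_numpy(float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs, importances = [], []
    oof = np.empty(len(y))
    for train, test in skf.split(X, y):
        if y[test].min() == y[test].max() or y[train].min() == y[train].max():
            raise StratificationError("a fold lacks one of the classes")
        model = _gbm(seed, hyper).fit(X[train], y[train])
        prob = model.predict_proba(X[test])[:, 1]
        fold_aucs.append(float(roc_auc_score(y[test], prob)))
        importances.append(model.feature_importances_)
        oof[test] = prob
    imp = np.mean(importances, axis=0)
    imp = imp / imp.sum() if imp.sum() > 0 else np.full(len(features), 1.0 / len(features))
    order = np.argsort(-imp, kind="stable")
    auc_arr = np.asarray(fold_aucs)
    mean, sd = float(auc_arr.mean()), float(auc_arr.std(ddof=1))
    half = 1.96 * sd / np.sqrt(k)
    final = _gbm(seed, hyper).fit(X, y)
    whiskers = _cohort_whiskers(table, features, label_column)
    report = ClassifierReport(
        candidates=candidates if candidates is not None else pd.DataFrame(
            {"feature": features}
        ),
        selected_features=[features[i] for i in order],
        importances={features[i]: float(imp[i]) for i in order},
        fold_aucs=fold_aucs,
        auc_mean=mean,
        auc_sd=sd,
        auc_ci95=(max(0.0, mean - half), min(1.0, mean + half)),
        pooled_auc=float(roc_auc_score(y, oof)),
        best_fold_auc=float(auc_arr.max()),
        seed=seed,
        hyperparameters=dict(hyper, k=k),
    )
    bundle = {
        "model": final,
        "features": features,
        "positive_label": positive_label,
        "whiskers": whiskers,
        "seed": seed,
        "hyperparameters": dict(hyper),
    }
    return report, bundle


def _cohort_whiskers(
    table: pd.DataFrame, features: list[str], label_column: str
) -> pd.DataFrame:
    """Per feature and class: min/q1/median/q3/max of the cohort values."""
    rows = []
    for feat in features:
        for lab, grp in table.groupby(label_column):
            v = grp[feat].to_numpy(float)
            rows.append({
                "feature": feat, "label": lab,
                "min": v.min(), "q1": np.percentile(v, 25),
                "median": np.percentile(v, 50), "q3": np.percentile(v, 75),
                "max": v.max(),
            })
    return pd.DataFrame(rows)


def predict_case(bundle: dict, feature_vector) -> tuple[float, pd.DataFrame]:
    """Probability of the positive class for one new case, plus overlay data.

    ``feature_vector`` is a mapping or Series holding at least the selected
    features.  The overlay table pairs the case value with the per-class
    cohort whisker statistics for each selected feature — the data behind a
    new-case whisker-plot display.
    """
    vec = pd.Series(feature_vector)
    missing = [f for f in bundle["features"] if f not in vec.index]
    if missing:
        raise ParameterError(f"missing feature(s): {', '.join(missing)}")
    x = vec[bundle["features"]].to_numpy(float).reshape(1, -1)
    prob = float(bundle["model"].predict_proba(x)[0, 1])
    overlay = bundle["whiskers"].copy()
    overlay["case_value"] = overlay.feature.map(vec)
    return prob, overlay


class AucFilteredBoostingClassifier(BaseEstimator, ClassifierMixin):
    """Univariate-filtered, RFE-pruned gradient-boosting tumor classifier.

    A scikit-learn compatible estimator combining the three stages:

    1. univariate screen — keep features with cross-validated AUC strictly
       above ``auc_min`` and Mann-Whitney p strictly below ``p_max``;
    2. backward recursive feature elimination to ``n_features`` features,
       scored by inner stratified CV accuracy of the boosted model;
    3. gradient boosting, evaluated with ``n_folds``-fold stratified CV and
       refit on all rows.

    Parameters follow scikit-learn conventions; fitted attributes carry a
    trailing underscore.  ``fit`` expects a feature DataFrame (columns are
    feature names) and string labels; the positive class is the
    oligodendroglioma by default.
    """

    def __init__(
        self,
        auc_min: float = 0.8,
        p_max: float = 0.005,
        n_features: int = 5,
        n_folds: int = 10,
        rfe_inner_folds: int = 5,
        n_estimators: int = 100,
        max_depth: int = 3,
        learning_rate: float = 0.1,
        subsample: float = 1.0,
        random_state: int = 0,
        positive_label: str = POSITIVE_LABEL,
    ):
        self.auc_min = auc_min
        self.p_max = p_max
        self.n_features = n_features
        self.n_folds = n_folds
        self.rfe_inner_folds = rfe_inner_folds
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.random_state = random_state
        self.positive_label = positive_label

    def _hyper(self) -> dict:
        return dict(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            learning_rate=self.learning_rate, subsample=self.subsample,
        )

    def fit(self, X: pd.DataFrame, y, stat_rows: pd.DataFrame | None = None):
        """Fit the three-stage classifier.

        ``stat_rows`` may carry a precomputed univariate statistics table
        (from :func:`perfquant.stats.feature_stat_table`); otherwise it is
        computed here with ``n_folds``-fold CV AUCs.
        """
        if not isinstance(X, pd.DataFrame):
            raise ParameterError("X must be a DataFrame of named features")
        if X.isna().any().any():
            raise ParameterError("feature table contains missing values")
        labels = np.asarray(y)
        table = X.copy()
        table["label"] = labels
        if stat_rows is None:
            stat_rows = gstats.feature_stat_table(
                table, X.columns, k=self.n_folds, seed=self.random_state,
                positive_label=self.positive_label,
            )
        candidates = filter_candidates(stat_rows, self.auc_min, self.p_max)
        cand_table = stat_rows[stat_rows.feature.isin(candidates)][
            ["feature", "auc_mean", "p_raw"]
        ].reset_index(drop=True)
        selected, passthrough = rfe_top5(
            table, candidates, seed=self.random_state,
            n_keep=self.n_features, inner_folds=self.rfe_inner_folds,
            positive_label=self.positive_label, hyperparameters=self._hyper(),
        )
        report, bundle = train_eval_gbm(
            table, selected, k=self.n_folds, seed=self.random_state,
            positive_label=self.positive_label, hyperparameters=self._hyper(),
            candidates=cand_table,
        )
        report.rfe_passthrough = passthrough
        self.candidate_features_ = candidates
        self.selected_features_ = report.selected_features
        self.feature_importances_ = report.importances
        self.report_ = report
        self.bundle_ = bundle
        self.classes_ = np.array(sorted(set(labels), key=str))
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "bundle_")
        probs = np.array([
            predict_case(self.bundle_, row)[0] for _, row in pd.DataFrame(X).iterrows()
        ])
        out = np.empty((probs.size, 2))
        for i, cls in enumerate(self.classes_):
            out[:, i] = probs if cls == self.positive_label else 1.0 - probs
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]
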