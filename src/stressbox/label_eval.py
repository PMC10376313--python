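"""Rule-based stress labeling, significance testing, and the evaluation
harness (cross-validation, pipeline + grid search, metrics, learning
curves, comparison-classifier adapters).

Labeling follows the physiological literature the study leaned on: a
sample is voted "stressed" by an LF/HF ratio above 3, a respiration rate
above 25 breaths/min, and by baseline-relative shifts (higher HR, LF,
ApEn, SD1 and GSR; lower HF, SD2, pNN50 and RMSSD than the subject's own
baseline phase).  The opposite directions vote "relaxed"; a feature equal
to baseline (or an LF/HF between 2 and 3, or a respiration rate of
exactly 25) abstains.  The final label is the majority of non-abstaining
votes; a tie resolves to relaxed, and a sample on which every rule
abstains raises rather than silently defaulting.

The comparison classifiers (SVM, naive Bayes, gradient boosting, XGBoost)
are thin adapters over scikit-learn / xgboost with the study's
hyperparameters; the package's own classifier is the CART tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.feature_selection import SelectKBest, chi2
from sklearn.metrics import accuracy_score, confusion_matrix, r2_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler

from .cart import CartClassifier
from .errors import ParameterError, UnlabeledSampleError, ValidationError
from .io_core import FeatureTable

logger = logging.getLogger(__name__)

#: Baseline-relative rules: +1 means an increase over baseline votes
#: "stressed" (and a decrease votes "relaxed"); -1 the reverse.
RELATIVE_STRESS_DIRECTIONS: dict[str, int] = {
    "MeanHR": +1,
    "LF_Lomb": +1,
    "HF_Lomb": -1,
    "ApEN": +1,
    "SD1": +1,
    "SD2": -1,
    "PNN50": -1,
    "RMSSD": -1,
    "GSR_mean": +1,
}


@dataclass
class LabelRuleSet:
    """Thresholds and directions for the binary stress-labeling rules."""

    lf_hf_feature: str = "LFHF_Lomb"
    lf_hf_stress_above: float = 3.0
    lf_hf_relax_below: float = 2.0
    resp_feature: str = "RESP_rate"
    resp_threshold: float = 25.0
    relative_directions: dict[str, int] = field(
        default_factory=lambda: dict(RELATIVE_STRESS_DIRECTIONS)
    )


def rule_label_binary(
    features: Mapping[str, float],
    baseline: Optional[Mapping[str, float]] = None,
    rules: Optional[LabelRuleSet] = None,
) -> int:
    """Label one feature set as stressed (1) or relaxed (0) by rule vote.

    Absolute-threshold rules (LF/HF, respiration rate) need no baseline;
    the relative rules compare against the subject's baseline-phase
    features and abstain when either value is missing or the two are
    equal.  Raises :class:`UnlabeledSampleError` when every rule abstains.
    """
    rules = rules or LabelRuleSet()
    stress = relax = 0

    lf_hf = features.get(rules.lf_hf_feature)
    if lf_hf is not None and np.isfinite(lf_hf):
        if lf_hf > rules.lf_hf_stress_above:
            stress += 1
        elif lf_hf < rules.lf_hf_relax_below:
            relax += 1

    resp = features.get(rules.resp_feature)
    if resp is not None and np.isfinite(resp):
        if resp > rules.resp_threshold:
            stress += 1
        elif resp < rules.resp_threshold:
            relax += 1

    if baseline is not None:
        for name, direction in rules.relative_directions.items():
            cur, base = features.get(name), baseline.get(name)
            if cur is None or base is None:
                continue
            if not (np.isfinite(cur) and np.isfinite(base)) or cur == base:
                continue
            shift = 1 if cur > base else -1
            if shift == direction:
                stress += 1
            else:
                relax += 1

    if stress == 0 and relax == 0:
        raise UnlabeledSampleError("every labeling rule abstained")
    return 1 if stress > relax else 0  # tie -> relaxed


def ttest_groups(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False
) -> tuple[float, float]:
    """Two-sample t test (Welch by default); returns (t, p).

    Degenerate zero-variance groups are handled by convention: equal
    constant groups give p = 1, shifted constant groups give p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float("inf") if np.mean(a) > np.mean(b) else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def is_significant(p: float, alpha: float = 0.05) -> bool:
    """Conventional reading: p <= alpha rejects the null of no difference."""
    return p <= alpha


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    mse: float = float("nan")
    r2: float = float("nan")
    confusion: Optional[np.ndarray] = None
    fold_scores: list[dict] = field(default_factory=list)
    best_params: Optional[dict] = None


def _precision_recall(y_true: np.ndarray, y_pred: np.ndarray, scheme: str) -> tuple[float, float]:
    if scheme == "binary":
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        prec = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
        rec = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
        return prec, rec
    # macro average over the classes present in y_true
    precs, recs = [], []
    for c in np.unique(y_true):
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        precs.append(tp / (tp + fp) if (tp + fp) > 0 else 0.0)
        recs.append(tp / (tp + fn) if (tp + fn) > 0 else 0.0)
    return float(np.mean(precs)), float(np.mean(recs))


def classification_metrics(y_true, y_pred, scheme: str = "binary") -> EvalReport:
    """Accuracy, precision/recall (positive-class or macro), MSE and R^2.

    MSE and R^2 treat the labels as integers (meaningful for the ordered
    0-4 stress levels).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ParameterError("need equal-length, non-empty label vectors")
    prec, rec = _precision_recall(y_true, y_pred, scheme)
    mse = float(np.mean((y_true - y_pred) ** 2))
    if np.all(y_true == y_pred):
        r2 = 1.0
    else:
        r2 = float(r2_score(y_true, y_pred))
    return EvalReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=prec,
        recall=rec,
        mse=mse,
        r2=r2,
        confusion=confusion_matrix(y_true, y_pred),
    )


def make_model(name: str, seed: int = 0):
    """Build a classifier by short name.

    ``cart`` is the package's own tree; the rest are adapters over
    established implementations with the study's hyperparameters
    (gradient boosting: learning rate 1, 100 estimators, depth 1; SVM:
    polynomial kernel of degree 3).
    """
    if name == "cart":
        return CartClassifier()
    if name == "dt":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(random_state=seed)
    if name == "svm":
        from sklearn.svm import SVC

        return SVC(kernel="poly", degree=3, gamma="scale", probability=True, random_state=seed)
    if name == "nb":
        from sklearn.naive_bayes import GaussianNB

        return GaussianNB()
    if name == "egb":
        from sklearn.ensemble import GradientBoostingClassifier

        return GradientBoostingClassifier(
            learning_rate=1.0, n_estimators=100, max_depth=1, random_state=seed
        )
    if name == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(n_estimators=100, random_state=seed, verbosity=0)
    raise ParameterError(f"unknown model {name!r}")


def _resolve_model(model, seed: int):
    return make_model(model, seed) if isinstance(model, str) else clone(model)


def cross_validate(
    model, table: FeatureTable, folds: int = 5, seed: int = 0
) -> EvalReport:
    """Stratified k-fold cross-validation of a classifier on a table.

    Folds with undefined precision/recall (no predicted or true
    positives) contribute NaN for that metric and are excluded from its
    mean with a warning.
    """
    if table.labels is None:
        raise ValidationError("cross-validation requires labels")
    if folds > table.n_samples:
        raise ParameterError(f"{folds} folds exceed {table.n_samples} samples")
    scheme = table.label_scheme if table.label_scheme != "none" else "binary"
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_scores = []
    for train_idx, test_idx in skf.split(table.values, table.labels):
        est = _resolve_model(model, seed)
        est.fit(table.values[train_idx], table.labels[train_idx])
        pred = np.asarray(est.predict(table.values[test_idx]), dtype=int)
        truth = table.labels[test_idx]
        prec, rec = _precision_recall(truth, pred, scheme)
        fold_scores.append(
            {
                "accuracy": float(accuracy_score(truth, pred)),
                "precision": prec,
                "recall": rec,
            }
        )
    accs = [s["accuracy"] for s in fold_scores]

    def _mean_defined(key: str) -> float:
        vals = np.asarray([s[key] for s in fold_scores], dtype=float)
        if np.isnan(vals).any():
            logger.warning(
                "%d fold(s) had undefined %s; excluded from the mean",
                int(np.isnan(vals).sum()), key,
            )
        vals = vals[~np.isnan(vals)]
        return float(np.mean(vals)) if len(vals) else float("nan")

    return EvalReport(
        accuracy=float(np.mean(accs)),
        precision=_mean_defined("precision"),
        recall=_mean_defined("recall"),
        fold_scores=fold_scores,
    )


def pipeline_grid_search(
    table: FeatureTable,
    model,
    param_grid: dict,
    folds: int = 5,
    seed: int = 0,
    select_k: int | str = "all",
) -> EvalReport:
    """Grid search over a min-max-scale -> chi2-select -> classify pipeline.

    Scaling precedes chi-squared scoring (chi2 needs nonnegative inputs)
    and both are re-fit inside every CV fold, so no test-fold statistics
    leak into training.  Model hyperparameters in the grid are addressed
    as ``model__<param>``.
    """
    if not param_grid:
        raise ParameterError("empty hyperparameter grid")
    if table.labels is None:
        raise ValidationError("grid search requires labels")
    pipe = Pipeline(
        [
            ("scale", MinMaxScaler()),
            ("select", SelectKBest(chi2, k=select_k)),
            ("model", _resolve_model(model, seed)),
        ]
    )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, param_grid, cv=skf, scoring="accuracy")
    search.fit(table.values, table.labels)
    scheme = table.label_scheme if table.label_scheme != "none" else "binary"
    pred = np.asarray(search.predict(table.values), dtype=int)
    prec, rec = _precision_recall(table.labels, pred, scheme)
    return EvalReport(
        accuracy=float(search.best_score_),
        precision=prec,
        recall=rec,
        best_params=dict(search.best_params_),
    )


#: Boosting grids as the study tuned them.
EGB_PAPER_PARAMS = {"learning_rate": 1.0, "n_estimators": 100, "max_depth": 1}
XGB_PAPER_GRID = {
    "model__colsample_bytree": [0.1],
    "model__gamma": [0.0, 0.1],
    "model__max_depth": [2, 4],
    "model__n_estimators": [50, 150],
    "model__learning_rate": [1.0],
}


def learning_curve(
    model,
    table: FeatureTable,
    train_fractions: Sequence[float],
    seed: int = 0,
    test_size: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Training and validation accuracy at increasing training-set sizes.

    A stratified held-out split is fixed once; for each fraction the model
    is fit on a stratified subsample of the training part and scored on
    both that subsample and the held-out part.  Fractions too small to
    keep one sample per class are skipped (NaN) with a warning.
    """
    if table.labels is None:
        raise ValidationError("learning curves require labels")
    fractions = np.asarray(train_fractions, dtype=float)
    if np.any((fractions <= 0) | (fractions > 1)):
        raise ParameterError("fractions must lie in (0, 1]")
    x_train, x_val, y_train, y_val = train_test_split(
        table.values,
        table.labels,
        test_size=test_size,
        random_state=seed,
        stratify=table.labels,
    )
    n_classes = len(np.unique(table.labels))
    train_scores = np.full(len(fractions), np.nan)
    val_scores = np.full(len(fractions), np.nan)
    for i, frac in enumerate(fractions):
        n_sub = int(round(frac * len(y_train)))
        if n_sub < n_classes:
            logger.warning("fraction %.3f leaves <1 sample per class; skipped", frac)
            continue
        if frac >= 1.0:
            xs, ys = x_train, y_train
        else:
            xs, _, ys, _ = train_test_split(
                x_train,
                y_train,
                train_size=frac,
                random_state=seed,
                stratify=y_train,
            )
        est = _resolve_model(model, seed)
        est.fit(xs, ys)
        train_scores[i] = accuracy_score(ys, est.predict(xs))
        val_scores[i] = accuracy_score(y_val, est.predict(x_val))
    return train_scores, val_scores
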