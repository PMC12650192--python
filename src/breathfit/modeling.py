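"""Class balancing, classifier training, cross-validation and metrics.

Binary fit classification with ``poor_fit`` as the positive class — the
safety-critical error is a poor fit passed off as a good one, so F1, ROC-AUC
and the false-negative rate are all reported with respect to ``poor_fit``.

Three model families are supported: random forests, RBF-kernel SVMs
(rescaled internally) and gradient-boosted trees (xgboost).  Class imbalance
is corrected with SMOTE — synthetic minority rows interpolated between a
minority sample and one of its k nearest minority neighbours — applied to
the *training* portion of each fold only; test folds are never resampled.

Two validation schemes: stratified k-fold (k = 5) over rows, and
leave-one-subject-out (LOSO), one fold per subject, which measures
subject-independent generalization.  Subject disjointness of LOSO folds is
asserted at runtime on every fold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import f1_score, make_scorer, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import ConfigError, ParameterError, TrainingError
from .features import feature_matrix
from .io import EvaluationReport, FoldResult

#: The designated positive (safety-critical) class.
POSITIVE_CLASS = "poor_fit"
NEGATIVE_CLASS = "fit"

MODEL_FAMILIES = ("random_forest", "svm_rbf", "gradient_boosted_trees")

#: Default hyperparameter grids (small, desk-scale; grid order is the
#: documented tie-break order).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "n_estimators": [100, 300],
        "max_depth": [None, 10],
        "min_samples_leaf": [1, 5],
    },
    "svm_rbf": {
        "C": [0.1, 1.0, 10.0],
        "gamma": ["scale", 0.01, 0.1],
    },
    "gradient_boosted_trees": {
        "learning_rate": [0.05, 0.1],
        "max_depth": [3, 6],
        "n_estimators": [100, 300],
        "subsample": [0.8, 1.0],
    },
}

#: Default (un-searched) hyperparameters per family.
DEFAULT_PARAMS: dict[str, dict] = {
    "random_forest": {"n_estimators": 300, "max_depth": None, "min_samples_leaf": 1},
    "svm_rbf": {"C": 10.0, "gamma": "scale"},
    "gradient_boosted_trees": {
        "learning_rate": 0.1,
        "max_depth": 6,
        "n_estimators": 300,
        "subsample": 1.0,
    },
}


@dataclass
class ModelSpec:
    """A model family with its hyperparameter grid and seed."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ConfigError(
                f"family {self.family!r} not in {MODEL_FAMILIES}"
            )
        if not self.grid:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if any(len(v) == 0 for v in self.grid.values()):
            raise ConfigError("hyperparameter grid must be non-empty")

    def grid_points(self) -> list[dict]:
        """Grid points in documented order (itertools.product over the grid's
        insertion order) — the tie-break order for grid search."""
        keys = list(self.grid)
        return [
            dict(zip(keys, values))
            for values in itertools.product(*(self.grid[k] for k in keys))
        ]


@dataclass
class FoldPlan:
    """Cross-validation plan: ``kfold`` (stratified, seeded shuffle) or
    ``loso`` (one fold per held-out subject; ``group_size`` > 1 holds out
    groups of subjects instead)."""

    scheme: str
    k: int = 5
    seed: int = 0
    group_size: int = 1
    folds: list[tuple[str, list[str], np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scheme not in ("kfold", "loso"):
            raise ConfigError(f"scheme must be 'kfold' or 'loso', got {self.scheme!r}")
        if self.scheme == "kfold" and self.k < 2:
            raise ConfigError(f"k must be >= 2, got {self.k}")
        if self.group_size < 1:
            raise ConfigError(f"group_size must be >= 1, got {self.group_size}")


def _encode(y: np.ndarray) -> np.ndarray:
    """Map string labels to {0: fit, 1: poor_fit}."""
    y = np.asarray(y)
    if y.dtype.kind in "OU":
        bad = set(np.unique(y)) - {POSITIVE_CLASS, NEGATIVE_CLASS}
        if bad:
            raise TrainingError(f"unknown labels {sorted(bad)}")
        return (y == POSITIVE_CLASS).astype(int)
    return y.astype(int)


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary dataset by synthetic minority oversampling.

    Each synthetic row lies on the segment between a randomly chosen
    minority row ``a`` and one of its ``k_neighbors`` nearest minority
    neighbours ``b``: ``a + u * (b - a)`` with ``u ~ U[0, 1]``.  Original
    rows are returned unchanged (first ``len(X)`` rows of the output).

    Raises
    ------
    TrainingError
        Single-class input.
    ParameterError
        Minority count <= ``k_neighbors``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TrainingError("SMOTE requires both classes present")
    if len(classes) > 2:
        raise TrainingError("SMOTE here is binary-only")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min <= k_neighbors:
        raise ParameterError(
            f"minority count {n_min} must exceed k_neighbors {k_neighbors}"
        )
    n_new = int(n_maj - n_min)
    if n_new == 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    Xmin = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xmin)
    _, neigh = nn.kneighbors(Xmin)  # column 0 is the point itself
    anchors = rng.integers(0, n_min, size=n_new)
    picks = rng.integers(1, k_neighbors + 1, size=n_new)
    u = rng.random(n_new)
    a = Xmin[anchors]
    b = Xmin[neigh[anchors, picks]]
    synth = a + u[:, None] * (b - a)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------


def make_folds(table: pd.DataFrame, plan: FoldPlan) -> FoldPlan:
    """Resolve a fold plan against a feature table.

    kfold: stratified by label with a seeded shuffle.  loso: one fold per
    distinct subject (or per group of ``group_size`` subjects in seeded
    order), the held-out subjects absent from the training rows.
    """
    _, y, subjects = feature_matrix(table)
    folds: list[tuple[str, list[str], np.ndarray]] = []
    if plan.scheme == "kfold":
        skf = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
        for i, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), _encode(y))):
            held = sorted(set(subjects[test_idx]))
            folds.append((f"fold{i + 1}", held, test_idx))
    else:
        uniq = sorted(set(subjects))
        if len(uniq) < 2:
            raise ConfigError("LOSO requires at least 2 subjects")
        if plan.group_size > 1:
            order = list(uniq)
            np.random.default_rng(plan.seed).shuffle(order)
            groups = [
                sorted(order[i : i + plan.group_size])
                for i in range(0, len(order), plan.group_size)
            ]
        else:
            groups = [[s] for s in uniq]
        for i, held in enumerate(groups):
            test_idx = np.flatnonzero(np.isin(subjects, held))
            folds.append((f"loso_{'+'.join(held)}", held, test_idx))
    resolved = FoldPlan(
        scheme=plan.scheme, k=plan.k, seed=plan.seed, group_size=plan.group_size
    )
    resolved.folds = folds
    return resolved


# ---------------------------------------------------------------------------
# Training and metrics
# ---------------------------------------------------------------------------


def _build_estimator(family: str, params: dict, seed: int):
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "svm_rbf":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="rbf", random_state=seed, **params)),
            ]
        )
    if family == "gradient_boosted_trees":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            **params,
        )
    raise ConfigError(f"unknown family {family!r}")


def train_classifier(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, params: dict | None = None
):
    """Fit one classifier of ``spec.family`` with ``params`` (or the family
    defaults).  Deterministic given ``spec.seed``.

    Raises
    ------
    TrainingError
        Degenerate (single-class) targets.
    """
    y01 = _encode(y)
    if len(np.unique(y01)) < 2:
        raise TrainingError("training targets contain a single class")
    model = _build_estimator(spec.family, params or DEFAULT_PARAMS[spec.family], spec.seed)
    model.fit(np.asarray(X, dtype=float), y01)
    return model


def predict_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores for the positive class (probability or margin)."""
    X = np.asarray(X, dtype=float)
    try:
        return model.predict_proba(X)[:, 1]
    except AttributeError:
        return model.decision_function(X)


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
) -> tuple[float, float | None, np.ndarray]:
    """F1 (positive class = poor_fit), ROC-AUC from scores, and a 2×2
    confusion matrix with rows = true (poor_fit, fit), cols = predicted.

    AUC is None when ``scores`` is absent or the test set has one class.
    """
    yt, yp = _encode(np.asarray(y_true)), _encode(np.asarray(y_pred))
    if len(yt) != len(yp) or (scores is not None and len(scores) != len(yt)):
        raise ParameterError("y_true, y_pred and scores must have equal length")
    f1 = float(np.clip(f1_score(yt, yp, pos_label=1, zero_division=0), 0.0, 1.0))
    auc = None
    if scores is not None and len(np.unique(yt)) == 2:
        # clip float round-off (trapezoid sums can exceed 1 by ~1 ulp)
        auc = float(np.clip(roc_auc_score(yt, scores), 0.0, 1.0))
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    cm = np.asarray([[tp, fn], [fp, tn]], dtype=int)
    return f1, auc, cm


def false_negative_rate(confusion: np.ndarray) -> float:
    """FN / (TP + FN): the fraction of true poor-fit cases passed as fit."""
    cm = np.asarray(confusion)
    tp, fn = int(cm[0, 0]), int(cm[0, 1])
    if tp + fn == 0:
        raise ParameterError("no positive cases: FN rate undefined")
    return fn / (tp + fn)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


def grid_search(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    inner_k: int = 3,
    smote: bool = True,
    k_neighbors: int = 5,
) -> dict:
    """Select the grid point maximizing mean inner-fold F1 (ties go to the
    first point in documented grid order).  Meant to be run on the training
    portion of an outer fold only; SMOTE, when enabled, is applied to each
    inner training split after the inner split is made.
    """
    points = spec.grid_points()
    if not points:
        raise ConfigError("empty hyperparameter grid")
    y01 = _encode(np.asarray(y))
    X = np.asarray(X, dtype=float)
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=spec.seed)
    splits = list(skf.split(X, y01))
    best_point, best_score = None, -np.inf
    for point in points:
        scores = []
        for tr, te in splits:
            Xtr, ytr = X[tr], y01[tr]
            if smote:
                Xtr, ytr = smote_balance(Xtr, ytr, k_neighbors=k_neighbors, seed=spec.seed)
            model = _build_estimator(spec.family, point, spec.seed)
            model.fit(Xtr, ytr)
            scores.append(f1_score(y01[te], model.predict(X[te]), zero_division=0))
        mean = float(np.mean(scores))
        if mean > best_score:  # strict: ties keep the earlier point
            best_point, best_score = point, mean
    return best_point


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def evaluate(
    table: pd.DataFrame,
    spec: ModelSpec,
    plan: FoldPlan,
    smote: bool = True,
    k_neighbors: int = 5,
    search: bool = False,
    segmentation_mode: str = "",
) -> EvaluationReport:
    """Cross-validated evaluation of one model family on a feature table.

    For each fold: SMOTE-balance the training portion only (the test fold is
    never resampled), optionally grid-search hyperparameters on the training
    portion, fit, and score the held-out rows.  LOSO subject disjointness is
    asserted on every fold.  The summary is mean ± SD of per-fold F1; a
    pooled confusion matrix over all folds is also reported.
    """
    X, y, subjects = feature_matrix(table)
    resolved = plan if plan.folds else make_folds(table, plan)
    y01 = _encode(y)
    fold_results = []
    pooled = np.zeros((2, 2), dtype=int)
    params = DEFAULT_PARAMS[spec.family]
    for fold_id, held, test_idx in resolved.folds:
        mask = np.zeros(len(y01), dtype=bool)
        mask[test_idx] = True
        train_idx = np.flatnonzero(~mask)
        if resolved.scheme == "loso":
            train_subj = set(subjects[train_idx])
            assert not (train_subj & set(held)), (
                f"leakage: held-out subjects {held} found in training rows"
            )
        Xtr, ytr = X[train_idx], y01[train_idx]
        if search:
            params = grid_search(
                spec, Xtr, ytr, smote=smote, k_neighbors=k_neighbors
            )
        if smote:
            Xtr, ytr = smote_balance(Xtr, ytr, k_neighbors=k_neighbors, seed=spec.seed)
        model = _build_estimator(spec.family, params, spec.seed)
        if len(np.unique(ytr)) < 2:
            raise TrainingError(f"fold {fold_id}: single-class training targets")
        model.fit(Xtr, ytr)
        Xte = X[test_idx]
        y_pred = model.predict(Xte)
        try:
            scores = predict_scores(model, Xte)
        except Exception:
            scores = None
        f1, auc, cm = compute_metrics(y01[test_idx], y_pred, scores)
        pooled += cm
        fold_results.append(
            FoldResult(
                fold_id=fold_id,
                test_subjects=list(held),
                test_size=len(test_idx),
                f1=f1,
                roc_auc=auc,
                confusion=cm.tolist(),
            )
        )
    f1s = np.asarray([f.f1 for f in fold_results])
    return EvaluationReport(
        scheme=resolved.scheme,
        folds=fold_results,
        f1_mean=float(f1s.mean()),
        f1_sd=float(f1s.std()),
        pooled_confusion=pooled.tolist(),
        model_family=spec.family,
        hyperparameters=dict(params),
        seed=spec.seed,
        segmentation_mode=segmentation_mode,
    )


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature mean ± SD drop in F1 over ``n_repeats`` permutations,
    sorted by descending mean drop."""
    if n_repeats < 1:
        raise ConfigError(f"n_repeats must be >= 1, got {n_repeats}")
    y01 = _encode(np.asarray(y))
    X = np.asarray(X, dtype=float)
    result = _sk_permutation_importance(
        model,
        X,
        y01,
        scoring=make_scorer(f1_score, pos_label=1, zero_division=0),
        n_repeats=n_repeats,
        random_state=seed,
        n_jobs=1,
    )
    names = feature_names or [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(
        {
            "feature": names,
            "mean_drop": result.importances_mean,
            "sd_drop": result.importances_std,
        }
    )
    return df.sort_values("mean_drop", ascending=False, kind="stable").reset_index(
        drop=True
    )
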