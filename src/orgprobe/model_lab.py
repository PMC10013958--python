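"""Training/evaluation lab: the (feature family x algorithm) comparison grid.

Protocol: a stratified 80/20 split of each task table, 5-fold stratified
cross-validation on the training partition, and test-set evaluation of every
(family, algorithm) cell with the same split.  Metrics are accuracy, AUC,
recall and precision; multiclass variants use support-weighted one-vs-rest
averaging, under which weighted recall is identically equal to accuracy.

Ten classical algorithms are available: decision tree, random forest,
AdaBoost, histogram gradient boosting, gradient boosting tree, XGBoost,
LightGBM, extremely randomized trees, logistic regression and linear-kernel
SVM.  Hyperparameters are library defaults (recorded in the report); linear
algorithms receive standardized inputs via a train-fitted scaler, tree
algorithms receive raw values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .featurize import FeatureMatrix
from .molecule_io import TaskTable


class ModelLabError(ValueError):
    pass


# ---------------------------------------------------------------------------
# algorithms

LINEAR_ALGORITHMS = frozenset({"logistic_regression", "linear_svm"})


def _make_estimator(algorithm: str, seed: int, hyperparameters: dict):
    hp = dict(hyperparameters or {})
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if algorithm == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hp)
    if algorithm == "hist_gbt":
        return HistGradientBoostingClassifier(random_state=seed, **hp)
    if algorithm == "gbt":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if algorithm == "xgboost":
        import xgboost as xgb

        hp.setdefault("n_jobs", 1)
        return xgb.XGBClassifier(random_state=seed, **hp)
    if algorithm == "lightgbm":
        import lightgbm as lgb

        hp.setdefault("n_jobs", 1)
        hp.setdefault("verbose", -1)
        return lgb.LGBMClassifier(random_state=seed, **hp)
    if algorithm == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, n_jobs=1, **hp)
    if algorithm == "logistic_regression":
        hp.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=seed, **hp)
    if algorithm == "linear_svm":
        hp.setdefault("kernel", "linear")
        hp.setdefault("probability", True)
        return SVC(random_state=seed, **hp)
    raise ModelLabError(f"unknown algorithm {algorithm!r}")


ALGORITHMS = (
    "decision_tree",
    "random_forest",
    "adaboost",
    "hist_gbt",
    "gbt",
    "xgboost",
    "lightgbm",
    "extra_trees",
    "logistic_regression",
    "linear_svm",
)


@dataclass
class ModelSpec:
    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ModelLabError(
                f"algorithm {self.algorithm!r} not in {ALGORITHMS}"
            )


# ---------------------------------------------------------------------------
# fitted model wrapper

@dataclass
class FittedModel:
    """A trained classifier plus the label/scale bookkeeping around it."""

    estimator: object
    classes: np.ndarray  # original labels, estimator trained on 0..k-1
    scaler: Optional[StandardScaler]
    spec: ModelSpec
    feature_names: list
    family: str

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def _prepare(self, X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            X = X.values
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ModelLabError(
                f"feature width mismatch: model expects {self.n_features}, got {X.shape[1]}"
            )
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Class-probability matrix with rows summing to 1, columns ordered
        as :attr:`classes`."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            proba = self.estimator.predict_proba(self._prepare(X))
        return np.asarray(proba, dtype=float)

    def predict(self, X) -> np.ndarray:
        """Argmax of the probabilities with a deterministic lowest-index
        tie-break."""
        proba = self.predict_proba(X)
        return self.classes[np.argmax(proba, axis=1)]


def train_model(
    spec: ModelSpec,
    X,
    y,
    feature_names: Optional[list] = None,
    family: str = "",
) -> FittedModel:
    if isinstance(X, FeatureMatrix):
        feature_names = feature_names or list(X.feature_names)
        family = family or X.family
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    y_enc = np.searchsorted(classes, y)
    scaler = None
    if spec.algorithm in LINEAR_ALGORITHMS:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    est = _make_estimator(spec.algorithm, spec.seed, spec.hyperparameters)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y_enc)
    names = feature_names if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])
    ]
    return FittedModel(est, classes, scaler, spec, list(names), family)


# ---------------------------------------------------------------------------
# metrics

def compute_metrics(
    y_true,
    y_pred,
    y_prob=None,
    averaging: str = "binary",
    classes: Optional[Sequence] = None,
    positive=None,
) -> dict:
    """Accuracy, AUC, recall, precision and the confusion matrix.

    ``averaging='binary'`` scores the positive class (``positive`` or the
    lexicographically larger label); ``'weighted'`` uses support-weighted
    one-vs-rest averages, so weighted recall equals accuracy.  AUC is the
    rank statistic of the positive-class probability; the multiclass AUC is
    the support-weighted one-vs-rest average, skipping (with a warning)
    classes absent from ``y_true``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    k = len(classes)

    if y_prob is not None:
        y_prob = np.asarray(y_prob, dtype=float)
        if y_prob.ndim == 2:
            sums = y_prob.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ModelLabError("probability rows must sum to 1 (tol 1e-9)")

    acc = float(np.mean(y_true == y_pred))
    confusion = np.zeros((k, k), dtype=int)
    pos_of = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        confusion[pos_of[t], pos_of[p]] += 1

    if averaging == "binary":
        if k > 2:
            raise ModelLabError("binary averaging with more than 2 classes")
        pos = positive if positive is not None else classes[-1]
        tp = int(np.sum((y_true == pos) & (y_pred == pos)))
        fn = int(np.sum((y_true == pos) & (y_pred != pos)))
        fp = int(np.sum((y_true != pos) & (y_pred == pos)))
        recall = tp / (tp + fn) if tp + fn else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        auc = np.nan
        if y_prob is not None:
            scores = y_prob[:, pos_of[pos]] if y_prob.ndim == 2 else y_prob
            yb = (y_true == pos).astype(int)
            if 0 < yb.sum() < len(yb):
                auc = float(roc_auc_score(yb, scores))
    elif averaging == "weighted":
        recalls, precisions, supports = [], [], []
        for i, c in enumerate(classes):
            support = int(np.sum(y_true == c))
            if support == 0:
                continue
            tp = int(np.sum((y_true == c) & (y_pred == c)))
            fp = int(np.sum((y_true != c) & (y_pred == c)))
            recalls.append(tp / support)
            precisions.append(tp / (tp + fp) if tp + fp else 0.0)
            supports.append(support)
        supports = np.asarray(supports, dtype=float)
        recall = float(np.average(recalls, weights=supports))
        precision = float(np.average(precisions, weights=supports))
        auc = np.nan
        if y_prob is not None:
            aucs, wts = [], []
            for i, c in enumerate(classes):
                yb = (y_true == c).astype(int)
                if 0 < yb.sum() < len(yb):
                    aucs.append(float(roc_auc_score(yb, y_prob[:, i])))
                    wts.append(yb.sum())
                elif yb.sum() == len(yb) or (yb.sum() == 0 and np.any(y_pred == c)):
                    warnings.warn(
                        f"class {c!r} skipped in OVR AUC (absent or universal)",
                        stacklevel=2,
                    )
            if aucs:
                auc = float(np.average(aucs, weights=np.asarray(wts, dtype=float)))
    else:
        raise ModelLabError(f"unknown averaging {averaging!r}")

    return {
        "acc": acc,
        "auc": auc,
        "recall": float(recall),
        "precision": float(precision),
        "confusion": confusion,
        "classes": classes,
    }


# ---------------------------------------------------------------------------
# splitting / cross-validation

@dataclass
class Split:
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


def split_dataset(
    y,
    train_fraction: float = 0.8,
    seed: int = 0,
    group_keys: Optional[Sequence] = None,
) -> Split:
    """Stratified random train/test split of label vector ``y``.

    Classes with fewer than 2 members stay entirely in train (with a
    warning).  With ``group_keys`` (e.g. InChIKeys) all rows sharing a key
    land on the same side, preventing cross-label duplicates from leaking
    between partitions.
    """
    y = np.asarray(y)
    n = len(y)
    if n == 0:
        raise ModelLabError("cannot split an empty table")
    if not 0.0 < train_fraction < 1.0:
        raise ModelLabError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)

    if group_keys is not None:
        group_keys = np.asarray(group_keys)
        uniq = pd.unique(group_keys)
        perm = rng.permutation(len(uniq))
        n_test_groups = int(round((1.0 - train_fraction) * len(uniq)))
        test_groups = set(uniq[perm[:n_test_groups]])
        test_mask = np.array([g in test_groups for g in group_keys])
        return Split(np.flatnonzero(~test_mask), np.flatnonzero(test_mask), seed)

    test_idx = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < 2:
            warnings.warn(
                f"class {c!r} has fewer than 2 members; kept entirely in train",
                stacklevel=2,
            )
            continue
        n_test = int(round((1.0 - train_fraction) * len(idx)))
        perm = rng.permutation(len(idx))
        test_idx.extend(idx[perm[:n_test]])
    test_idx = np.sort(np.asarray(test_idx, dtype=int))
    train_mask = np.ones(n, dtype=bool)
    train_mask[test_idx] = False
    return Split(np.flatnonzero(train_mask), test_idx, seed)


def _stratified_folds(y, folds: int, seed: int) -> list:
    """Deterministic stratified fold assignment; returns list of index arrays."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    offset = 0
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        perm = rng.permutation(idx)
        for pos, i in enumerate(perm):
            assignment[i] = (pos + offset) % folds
        offset += len(idx)  # rotate start fold so small classes spread out
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def cross_validate(
    spec: ModelSpec,
    X,
    y,
    folds: int = 5,
    seed: int = 0,
    averaging: Optional[str] = None,
    positive=None,
    oversample: bool = False,
    smote_k: int = 5,
) -> dict:
    """Stratified k-fold CV; per-fold metrics aggregated as mean and SD.

    ``oversample`` applies SMOTE to each fold's training side only, so no
    synthetic sample is ever evaluated.
    """
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ModelLabError("folds must be >= 2")
    min_class = min(np.bincount(np.searchsorted(np.unique(y), y)))
    if min_class < folds:
        warnings.warn(
            f"smallest class has {min_class} members; reducing folds to {max(2, min_class)}",
            stacklevel=2,
        )
        folds = max(2, int(min_class))
    classes = np.unique(y)
    if averaging is None:
        averaging = "binary" if len(classes) == 2 else "weighted"

    fold_idx = _stratified_folds(y, folds, seed)
    per_fold = []
    for f, test_idx in enumerate(fold_idx):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        if len(np.unique(y[test_idx])) < 2 and averaging == "binary":
            warnings.warn(f"fold {f} degenerate (single class); skipped", stacklevel=2)
            continue
        Xtr, ytr = X[train_idx], y[train_idx]
        if oversample and len(classes) == 2:
            from .imbalance import smote as _smote

            res = _smote(Xtr, ytr, k=smote_k, seed=seed + f)
            Xtr, ytr = res.X_out, res.y_out
        model = train_model(spec, Xtr, ytr)
        proba = model.predict_proba(X[test_idx])
        pred = model.predict(X[test_idx])
        m = compute_metrics(
            y[test_idx], pred, proba, averaging=averaging,
            classes=model.classes, positive=positive,
        )
        per_fold.append(m)
    if not per_fold:
        raise ModelLabError("all folds degenerate")
    out = {"folds": len(per_fold), "fold_indices": fold_idx}
    for key in ("acc", "auc", "recall", "precision"):
        vals = np.asarray([m[key] for m in per_fold], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[key] = (float(vals.mean()), float(vals.std())) if len(vals) else (np.nan, np.nan)
    return out


# ---------------------------------------------------------------------------
# grid comparison

@dataclass
class CellResult:
    family: str
    algorithm: str
    cv: dict = field(default_factory=dict)       # metric -> (mean, sd)
    test: dict = field(default_factory=dict)     # metric -> value
    confusion: Optional[np.ndarray] = None
    model: Optional[FittedModel] = None
    error: Optional[str] = None


@dataclass
class EvalReport:
    task: str
    cells: Dict[Tuple[str, str], CellResult]
    split: Split
    seed: int

    def best_cell(self) -> CellResult:
        """Best cell by test accuracy; CV accuracy then (family, algorithm)
        name order break ties."""
        ok = [c for c in self.cells.values() if c.error is None]
        if not ok:
            raise ModelLabError("no successful grid cell")
        return min(
            ok,
            key=lambda c: (-c.test["acc"], -c.cv["acc"][0], c.family, c.algorithm),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (fam, algo), c in sorted(self.cells.items()):
            row = {"family": fam, "algorithm": algo, "error": c.error or ""}
            for met in ("acc", "auc", "recall", "precision"):
                if c.cv:
                    row[f"cv_{met}"] = c.cv[met][0]
                    row[f"cv_{met}_sd"] = c.cv[met][1]
                if c.test:
                    row[f"test_{met}"] = c.test[met]
            rows.append(row)
        return pd.DataFrame(rows)

    def heatmap_frame(self, metric: str = "test_acc") -> pd.DataFrame:
        df = self.to_frame()
        return df.pivot(index="family", columns="algorithm", values=metric)


def grid_compare(
    table: TaskTable,
    features: Dict[str, FeatureMatrix],
    specs: Sequence[ModelSpec],
    seed: int = 0,
    train_fraction: float = 0.8,
    folds: int = 5,
    positive=None,
    oversample: bool = False,
    keep_models: bool = True,
) -> EvalReport:
    """Evaluate every (feature family x algorithm) cell on the same split.

    A failing cell is marked with its error and the grid continues.
    """
    if not features or not specs:
        raise ModelLabError("need at least one family and one spec")
    y = np.asarray(table.labels)
    split = split_dataset(y, train_fraction=train_fraction, seed=seed)
    averaging = "binary" if len(np.unique(y)) == 2 else "weighted"

    cells = {}
    for fam, fm in features.items():
        if fm.shape[0] != len(y):
            raise ModelLabError(
                f"feature matrix {fam} has {fm.shape[0]} rows for {len(y)} labels"
            )
        X = fm.values
        for spec in specs:
            cell = CellResult(family=fam, algorithm=spec.algorithm)
            try:
                cell.cv = cross_validate(
                    spec, X[split.train_idx], y[split.train_idx],
                    folds=folds, seed=seed, averaging=averaging,
                    positive=positive, oversample=oversample,
                )
                Xtr, ytr = X[split.train_idx], y[split.train_idx]
                if oversample and len(np.unique(y)) == 2:
                    from .imbalance import smote as _smote

                    res = _smote(Xtr, ytr, seed=seed)
                    Xtr, ytr = res.X_out, res.y_out
                model = train_model(
                    spec, Xtr, ytr, feature_names=list(fm.feature_names), family=fam
                )
                proba = model.predict_proba(X[split.test_idx])
                pred = model.predict(X[split.test_idx])
                m = compute_metrics(
                    y[split.test_idx], pred, proba, averaging=averaging,
                    classes=model.classes, positive=positive,
                )
                cell.test = {k: m[k] for k in ("acc", "auc", "recall", "precision")}
                cell.confusion = m["confusion"]
                if keep_models:
                    cell.model = model
            except Exception as exc:  # cell failure must not kill the grid
                cell.error = f"{type(exc).__name__}: {exc}"
            cells[(fam, spec.algorithm)] = cell
    return EvalReport(task=table.task, cells=cells, split=split, seed=seed)
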