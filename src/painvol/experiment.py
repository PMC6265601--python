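"""Prediction experiments: four classifiers, stratified CV, class balancing.

Four model families predict the month-6 volatility class from the 130
month-1 features: logistic regression with a ridge (L2) penalty, logistic
regression with the LASSO (L1), Random Forests (100 trees, ``mtry =
round(2·sqrt(n_features))`` features per split) and an RBF-kernel SVM with
library-default cost and width.  Evaluation is stratified 5-fold
cross-validation — every user is tested exactly once — and the class
imbalance (roughly 78% low / 22% high volatility) is optionally addressed
by randomly subsampling the majority class *within each training fold* to
the minority size, repeated ``n_subsamples`` times over fixed folds so the
subsampling variance is isolated from the fold split.

Three accuracy measures are reported with the high-volatility class as the
positive class::

    acc_low     = 100 * TN / (TN + FP)
    acc_high    = 100 * TP / (TP + FN)
    acc_overall = 100 * (TP + TN) / N

Preprocessing (one-hot of categoricals, standardisation of non-binary
numeric columns) and the internal penalty search for the logistic models
use training folds only; test indices never enter those computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVC

METHODS = ("ridge_logistic", "lasso_logistic", "random_forest", "svm_rbf")
POSITIVE_CLASS = "high"

__all__ = [
    "METHODS",
    "ExperimentSpec",
    "SubsampleResult",
    "ExperimentResult",
    "stratified_kfold",
    "balance_training",
    "fit_predict",
    "run_experiment",
]


@dataclass(frozen=True)
class ExperimentSpec:
    """Configuration of one prediction experiment."""

    method: str
    balanced: bool = False
    n_subsamples: int = 3
    k_folds: int = 5
    seed: int = 0
    rf_n_trees: int = 100
    rf_mtry: int | None = None          # default: round(2*sqrt(n_features))
    penalty_grid: tuple[float, ...] = tuple(np.logspace(-3, 2, 10))
    penalty_cv_folds: int = 10
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; use one of {METHODS}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.balanced and self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1 in balanced mode")


@dataclass(frozen=True)
class SubsampleResult:
    """Confusion counts and the three accuracies for one evaluation pass."""

    subsample: int
    tp: int
    tn: int
    fp: int
    fn: int
    predictions: tuple[str, ...]

    @property
    def acc_low(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def acc_high(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def acc_overall(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return 100.0 * (self.tp + self.tn) / total


@dataclass(frozen=True)
class ExperimentResult:
    method: str
    balanced: bool
    subsamples: tuple[SubsampleResult, ...]

    def to_frame(self) -> pd.DataFrame:
        """One row per (measure, subsample), mirroring the results tables."""
        rows = []
        for s in self.subsamples:
            rows.append(
                {
                    "method": self.method,
                    "balanced": self.balanced,
                    "subsample": s.subsample + 1,
                    "acc_low": s.acc_low,
                    "acc_high": s.acc_high,
                    "acc_overall": s.acc_overall,
                }
            )
        return pd.DataFrame(rows)

    def mean_accuracies(self) -> dict[str, float]:
        return {
            "acc_low": float(np.mean([s.acc_low for s in self.subsamples])),
            "acc_high": float(np.mean([s.acc_high for s in self.subsamples])),
            "acc_overall": float(
                np.mean([s.acc_overall for s in self.subsamples])
            ),
        }


def stratified_kfold(
    labels: Sequence[str], k: int, seed: int | None = None
) -> list[np.ndarray]:
    """k disjoint test index sets preserving class proportions per fold.

    Every index appears in exactly one test set, and each fold's class
    counts are within one member of an even split of that class.
    """
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(len(y)), y)]


def balance_training(
    train_idx: np.ndarray,
    labels: Sequence[str],
    seed: int | None = None,
) -> np.ndarray:
    """Subsample the majority class among training indices to minority size.

    The minority class is kept whole; majority instances are drawn without
    replacement.  Returns the balanced index set in sorted order.
    """
    y = np.asarray(labels)
    train_idx = np.asarray(train_idx)
    classes, counts = np.unique(y[train_idx], return_counts=True)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")
    minority = classes[counts.argmin()]
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = [train_idx[y[train_idx] == minority]]
    for cls in classes:
        if cls == minority:
            continue
        pool = train_idx[y[train_idx] == cls]
        if pool.size > n_min:
            pool = rng.choice(pool, size=n_min, replace=False)
        keep.append(pool)
    return np.sort(np.concatenate(keep))


def _build_preprocessor(X: pd.DataFrame) -> ColumnTransformer:
    cat_cols = [c for c in X.columns if X[c].dtype == object]
    num_cols = [c for c in X.columns if c not in cat_cols]
    binary_cols = [
        c for c in num_cols if set(pd.unique(X[c])) <= {0, 1, 0.0, 1.0}
    ]
    cont_cols = [c for c in num_cols if c not in binary_cols]
    return ColumnTransformer(
        [
            ("cat", OneHotEncoder(handle_unknown="ignore"), cat_cols),
            ("num", StandardScaler(), cont_cols),
            ("bin", "passthrough", binary_cols),
        ]
    )


def _select_c_1se(
    l1_ratio: float,
    X: np.ndarray,
    y: np.ndarray,
    spec: ExperimentSpec,
    seed: int,
) -> float:
    """Pick the strongest penalty within one standard error of the best.

    glmnet-style rule: score each candidate C by internal stratified CV on
    the training data, then take the smallest C (most regularisation)
    whose mean accuracy is within one SE of the best mean.
    """
    _, counts = np.unique(y, return_counts=True)
    n_folds = int(min(spec.penalty_cv_folds, counts.min()))
    if n_folds < 2:
        return 1.0
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    grid = sorted(spec.penalty_grid)
    means, sems = [], []
    for c in grid:
        clf = LogisticRegression(
            C=c, l1_ratio=l1_ratio, solver="liblinear", max_iter=5000
        )
        scores = cross_val_score(clf, X, y, cv=cv)
        means.append(scores.mean())
        sems.append(scores.std(ddof=1) / np.sqrt(n_folds))
    best = int(np.argmax(means))
    cutoff = means[best] - sems[best]
    for c, m in zip(grid, means):
        if m >= cutoff:
            return float(c)
    return float(grid[best])


def fit_predict(
    spec: ExperimentSpec,
    X_train: pd.DataFrame,
    y_train: Sequence[str],
    X_test: pd.DataFrame,
    seed: int | None = None,
) -> np.ndarray:
    """Fit the spec's model on training data and predict test labels.

    Categorical columns are one-hot encoded and non-binary numeric columns
    standardised, both fit on the training data only.
    """
    y = np.asarray(y_train)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    seed = spec.seed if seed is None else seed
    pre = _build_preprocessor(X_train)
    Xt = np.asarray(pre.fit_transform(X_train), dtype=float)
    Xe = np.asarray(pre.transform(X_test), dtype=float)
    if spec.method in ("ridge_logistic", "lasso_logistic"):
        l1_ratio = 0.0 if spec.method == "ridge_logistic" else 1.0
        c = _select_c_1se(l1_ratio, Xt, y, spec, seed)
        clf = LogisticRegression(
            C=c, l1_ratio=l1_ratio, solver="liblinear", max_iter=5000
        )
    elif spec.method == "random_forest":
        mtry = spec.rf_mtry
        if mtry is None:
            mtry = int(round(2.0 * np.sqrt(X_train.shape[1])))
        clf = RandomForestClassifier(
            n_estimators=spec.rf_n_trees,
            max_features=min(mtry, Xt.shape[1]),
            random_state=seed,
        )
    elif spec.method == "svm_rbf":
        clf = SVC(kernel="rbf", C=spec.svm_c, gamma=spec.svm_gamma)
    else:  # pragma: no cover — guarded by ExperimentSpec
        raise ValueError(f"unknown method {spec.method!r}")
    clf.fit(Xt, y)
    return clf.predict(Xe)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    pos = y_true == POSITIVE_CLASS
    pred_pos = y_pred == POSITIVE_CLASS
    tp = int(np.sum(pos & pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    return tp, tn, fp, fn


def run_experiment(
    X: pd.DataFrame,
    labels: Sequence[str],
    spec: ExperimentSpec,
) -> ExperimentResult:
    """Cross-validated prediction with optional majority-class subsampling.

    Unbalanced mode is a single pass over the folds.  Balanced mode runs
    ``spec.n_subsamples`` passes, drawing a fresh majority subsample per
    training fold each pass while the folds themselves stay fixed.  Test
    folds are never subsampled.
    """
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("features and labels differ in length")
    folds = stratified_kfold(y, spec.k_folds, spec.seed)
    all_idx = np.arange(len(y))
    n_passes = spec.n_subsamples if spec.balanced else 1
    passes = []
    for s in range(n_passes):
        y_pred = np.empty(len(y), dtype=object)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            if spec.balanced:
                train_idx = balance_training(
                    train_idx, y, seed=_derive_seed(spec.seed, s, f)
                )
            y_pred[test_idx] = fit_predict(
                spec,
                X.iloc[train_idx],
                y[train_idx],
                X.iloc[test_idx],
                seed=_derive_seed(spec.seed, s, f, 1),
            )
        tp, tn, fp, fn = _confusion(y, y_pred.astype(str))
        passes.append(
            SubsampleResult(
                subsample=s, tp=tp, tn=tn, fp=fp, fn=fn,
                predictions=tuple(y_pred.astype(str)),
            )
        )
    return ExperimentResult(
        method=spec.method, balanced=spec.balanced, subsamples=tuple(passes)
    )


def _derive_seed(base: int, *parts: int) -> int:
    out = np.random.SeedSequence([base, *parts]).generate_state(1)[0]
    return int(out % (2**31))
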