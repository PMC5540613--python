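"""Taster-status classification: KNN/SVM over repeated stratified CV.

Four classification problems are supported: NT vs ST (medium tasters
dropped), NT vs Tasters (MT and ST merged), the three-class NT/MT/ST
problem, and the TAS2R38 diplotype problem (PAV/PAV, PAV/AVI, AVI/AVI).
Accuracy is estimated with a stratified 20-times 10-fold cross-validation;
each of the 200 folds contributes one accuracy value, summarized by mean,
SD and boxplot statistics with the q3 + 1.5*IQR outlier rule (outliers are
flagged but never removed).

Features are z-scored with training-fold statistics before either
classifier: cosine and RBF distances are meaningless on raw features whose
units range from mV to mV^2*s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC, NuSVC

from .errors import ConfigurationError
from .features import FEATURE_COLUMNS, select_combo

PROBLEMS = ("nt_vs_st", "nt_vs_tasters", "nt_vs_mt_vs_st", "diplotype")


@dataclass
class ClassifierSpec:
    """Classifier family and hyperparameters (deliberately default-valued)."""

    kind: str = "knn"  # knn | svm
    metric: str = "cubic"  # knn: cubic | cosine
    k: int = 10
    svm_c: float = 1.0
    svm_gamma: float = 1.0
    svm_variant: str = "c"  # c | nu
    svm_nu: float = 0.5
    standardize: bool = True


@dataclass
class CVReport:
    """Per-fold accuracies of a repeated stratified CV and their summary."""

    fold_accuracies: np.ndarray
    mean: float
    sd: float
    quartiles: tuple[float, float, float]
    outliers: np.ndarray
    per_class_accuracy: dict[str, float]
    seed: int
    repeat_means: np.ndarray = field(default_factory=lambda: np.array([]))
    confusion: pd.DataFrame | None = None


def _zscore_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return mu, sd


def _pairwise_distance(A: np.ndarray, B: np.ndarray, metric: str) -> np.ndarray:
    """Distances between rows of A (test) and rows of B (train)."""
    if metric == "cubic":
        diff = np.abs(A[:, None, :] - B[None, :, :])
        return (diff**3).sum(axis=2) ** (1.0 / 3.0)
    if metric == "cosine":
        na = np.linalg.norm(A, axis=1, keepdims=True)
        nb = np.linalg.norm(B, axis=1, keepdims=True)
        na = np.where(na == 0.0, 1.0, na)
        nb = np.where(nb == 0.0, 1.0, nb)
        return 1.0 - (A / na) @ (B / nb).T
    raise ConfigurationError(f"unknown KNN metric {metric!r}")


def knn_classify(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    k: int = 10,
    metric: str = "cubic",
) -> np.ndarray:
    """k-nearest-neighbour prediction with cosine or cubic distance.

    Majority vote among the k nearest training rows; vote ties are broken
    by the label of the single nearest neighbour among the tied classes,
    which is deterministic and distance-respecting.
    """
    X_train = np.asarray(X_train, float)
    X_test = np.asarray(X_test, float)
    y_train = np.asarray(y_train)
    if k > len(X_train):
        raise ConfigurationError(f"k={k} exceeds training size {len(X_train)}")
    dist = _pairwise_distance(X_test, X_train, metric)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    preds = []
    for row in order:
        labels = y_train[row]
        uniq, counts = np.unique(labels, return_counts=True)
        winners = uniq[counts == counts.max()]
        if len(winners) == 1:
            preds.append(winners[0])
        else:
            # nearest single neighbour whose label is among the tied classes
            tied = set(winners.tolist())
            preds.append(next(lab for lab in labels if lab in tied))
    return np.asarray(preds)


def svm_classify(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    C: float = 1.0,
    gamma: float = 1.0,
    variant: str = "c",
    nu: float = 0.5,
) -> np.ndarray:
    """RBF-kernel SVM prediction (one-vs-one for multiclass problems)."""
    if len(np.unique(y_train)) < 2:
        raise ConfigurationError("SVM training set has a single class")
    if variant == "nu":
        clf = NuSVC(nu=nu, kernel="rbf", gamma=gamma)
    elif variant == "c":
        clf = SVC(C=C, kernel="rbf", gamma=gamma)
    else:
        raise ConfigurationError(f"unknown SVM variant {variant!r}")
    clf.fit(X_train, y_train)
    return clf.predict(X_test)


def _predict(spec: ClassifierSpec, X_train, y_train, X_test) -> np.ndarray:
    if spec.standardize:
        mu, sd = _zscore_params(X_train)
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd
    if spec.kind == "knn":
        return knn_classify(X_train, y_train, X_test, k=spec.k, metric=spec.metric)
    if spec.kind == "svm":
        return svm_classify(
            X_train,
            y_train,
            X_test,
            C=spec.svm_c,
            gamma=spec.svm_gamma,
            variant=spec.svm_variant,
            nu=spec.svm_nu,
        )
    raise ConfigurationError(f"unknown classifier kind {spec.kind!r}")


def summarize_boxstats(values: np.ndarray) -> dict:
    """Quartiles (linear-interpolation percentiles) and IQR-rule outliers.

    Outliers are values above q3 + 1.5*(q3 - q1) or below q1 - 1.5*(q3 - q1);
    they are flagged here but retained in every mean/SD elsewhere.
    """
    values = np.asarray(values, float)
    if len(values) == 0:
        raise ConfigurationError("cannot summarize an empty vector")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    mask = (values > q3 + 1.5 * iqr) | (values < q1 - 1.5 * iqr)
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "outliers": values[mask],
    }


def stratified_repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    k: int = 10,
    repeats: int = 20,
    seed: int = 0,
) -> CVReport:
    """Stratified, repeated k-fold CV returning all repeats*k fold accuracies.

    Standardization statistics are computed on each training fold only.
    When the smallest class has fewer members than ``k`` the fold count is
    reduced to that size with a warning (graceful degradation).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ConfigurationError("need at least two classes for cross-validation")
    n_splits = int(min(k, counts.min()))
    if n_splits < k:
        warnings.warn(
            f"smallest class has {counts.min()} members < k={k}; "
            f"using {n_splits}-fold stratification",
            stacklevel=2,
        )
    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=repeats, random_state=seed)
    accs = []
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for train_idx, test_idx in cv.split(X, y):
        pred = _predict(spec, X[train_idx], y[train_idx], X[test_idx])
        truth = y[test_idx]
        accs.append(float(np.mean(pred == truth)))
        for t, p in zip(truth, pred):
            conf.loc[t, p] += 1
    accs = np.asarray(accs)
    box = summarize_boxstats(accs)
    per_class = {
        str(c): float(conf.loc[c, c] / conf.loc[c].sum()) for c in classes
    }
    return CVReport(
        fold_accuracies=accs,
        mean=float(accs.mean()),
        sd=float(accs.std(ddof=1)),
        quartiles=(box["q1"], box["median"], box["q3"]),
        outliers=box["outliers"],
        per_class_accuracy=per_class,
        seed=seed,
        repeat_means=accs.reshape(repeats, n_splits).mean(axis=1),
        confusion=conf,
    )


def map_labels(meta: pd.DataFrame, problem: str) -> pd.Series:
    """Class labels for a problem; NaN marks subjects to drop."""
    if problem == "nt_vs_st":
        return meta["taster_label"].map({"NT": "NT", "ST": "ST"})
    if problem == "nt_vs_tasters":
        return meta["taster_label"].map({"NT": "NT", "MT": "Taster", "ST": "Taster"})
    if problem == "nt_vs_mt_vs_st":
        return meta["taster_label"].map({"NT": "NT", "MT": "MT", "ST": "ST"})
    if problem == "diplotype":
        return meta["diplotype"].map(
            {"PAV/PAV": "PAV/PAV", "PAV/AVI": "PAV/AVI", "AVI/AVI": "AVI/AVI"}
        )
    raise ConfigurationError(f"unknown problem {problem!r}; choose from {PROBLEMS}")


def run_problem(
    table: pd.DataFrame,
    problem: str,
    spec: ClassifierSpec,
    combo: str = "best1",
    k: int = 10,
    repeats: int = 20,
    seed: int = 0,
) -> CVReport:
    """Assemble a classification problem from a feature table and run CV.

    ``table`` needs the columns f1..f7 plus taster_label/diplotype.
    Subjects outside the problem's classes are dropped.
    """
    labels = map_labels(table, problem)
    keep = labels.notna()
    if keep.sum() == 0 or labels[keep].nunique() < 2:
        raise ConfigurationError(
            f"problem {problem!r}: fewer than two non-empty classes in the cohort"
        )
    F = table.loc[keep, FEATURE_COLUMNS].to_numpy(float)
    X = np.stack([select_combo(row, combo) for row in F])
    y = labels[keep].to_numpy()
    return stratified_repeated_cv(X, y, spec, k=k, repeats=repeats, seed=seed)
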