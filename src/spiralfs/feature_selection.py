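"""Wrapper feature selection on top of the whale optimizers.

A candidate feature subset is encoded as a continuous position in the unit
hypercube; components above 0.5 select the corresponding feature.  Subsets
are scored by

    fitness = alpha * ErrorRate + (1 - alpha) * R / N_features

where ``ErrorRate`` is the stratified 5-fold cross-validated
misclassification rate of a k-NN (k = 5) on the training partition, ``R``
the number of selected features, and ``alpha = 0.99``: accuracy dominates,
with a mild pressure toward small subsets.  The fitness is minimized.  Data
enter through an 80/20 stratified train/test split; the test fifth is
touched exactly once, at the end, to report held-out accuracy.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .mswoa import MSWOAConfig, mswoa_run
from .woa import woa_run

__all__ = [
    "FitnessSpec",
    "FSResult",
    "load_dataset",
    "binarize",
    "subset_fitness",
    "cv_error",
    "select_features",
]


@dataclass
class FitnessSpec:
    """Weights and classifier settings of the subset-scoring function."""

    alpha: float = 0.99
    threshold: float = 0.5
    k_neighbors: int = 5
    folds: int = 5
    classifier: str = "knn"  # "knn" for the wrapper fitness, "svm" for the fall demo

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.classifier not in ("knn", "svm"):
            raise ValueError("classifier must be 'knn' or 'svm'")

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha


@dataclass
class FSResult:
    """Outcome of one select-and-evaluate run."""

    mask: np.ndarray
    fitness: float
    history: list[float]
    test_accuracy: float  # percent on the held-out 20% split
    cv_accuracy: float  # percent, 1 - CV error of the best mask on the train split
    n_selected: int
    n_features: int
    wall_time: float
    seed: int
    n_evaluations: int = 0

    def to_dict(self) -> dict:
        return {
            "selected_features": np.flatnonzero(self.mask).tolist(),
            "n_selected": self.n_selected,
            "n_features": self.n_features,
            "fitness": self.fitness,
            "test_accuracy_pct": round(self.test_accuracy, 4),
            "cv_accuracy_pct": round(self.cv_accuracy, 4),
            "wall_time_s": self.wall_time,
            "seed": self.seed,
            "n_evaluations": self.n_evaluations,
        }

    def save(self, json_path, history_csv_path=None) -> None:
        with open(json_path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        if history_csv_path is not None:
            pd.DataFrame({"iteration": range(len(self.history)),
                          "best_fitness": self.history}).to_csv(history_csv_path, index=False)


def load_dataset(path, label_column: str | None = None, sep: str | None = None,
                 header: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Read a delimited samples x features matrix with one label column.

    The label column is taken by name when given, else the last column.
    The delimiter is sniffed by pandas when not supplied.
    """
    df = pd.read_csv(path, sep=sep, header=0 if header else None, engine="python")
    if label_column is None:
        label_column = df.columns[-1]
    y = df[label_column].to_numpy()
    x = df.drop(columns=[label_column]).to_numpy(dtype=float)
    return x, y


def binarize(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Feature mask: strictly above-threshold components are selected."""
    position = np.asarray(position, float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position must be finite")
    return position > threshold


def subset_fitness(error_rate: float, n_selected: int, n_total: int,
                   spec: FitnessSpec | None = None) -> float:
    """Weighted objective ``alpha * error + beta * R/N``; empty subsets score 1.

    An empty subset is assigned the worst attainable value, 1.0, so the
    optimizer is driven away from it without any position repair.
    """
    spec = spec or FitnessSpec()
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    if not 0 <= n_selected <= n_total or n_total < 1:
        raise ValueError("invalid feature counts")
    if n_selected == 0:
        return 1.0
    return spec.alpha * error_rate + spec.beta * n_selected / n_total


def _minmax_fit(x: np.ndarray):
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    span[span == 0.0] = 1.0
    return lo, span


def _knn_predict(x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray,
                 k: int) -> np.ndarray:
    """Euclidean k-NN majority vote; ties go to the nearest neighbor's class."""
    classes, y_idx = np.unique(y_train, return_inverse=True)
    dist = cdist(x_test, x_train)
    order = np.argsort(dist, axis=1, kind="stable")[:, :k]
    votes = y_idx[order]
    pred = np.empty(len(x_test), dtype=int)
    for i in range(len(x_test)):
        counts = np.bincount(votes[i], minlength=len(classes))
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if winners.size == 1:
            pred[i] = winners[0]
        else:
            # nearest neighbor whose class is among the tied winners
            in_tie = np.isin(votes[i], winners)
            pred[i] = votes[i][np.argmax(in_tie)]
    return classes[pred]


def _fold_error(x_tr: np.ndarray, y_tr: np.ndarray, x_va: np.ndarray,
                y_va: np.ndarray, spec: FitnessSpec) -> float:
    lo, span = _minmax_fit(x_tr)  # scale on the training fold only
    x_tr = (x_tr - lo) / span
    x_va = (x_va - lo) / span
    if spec.classifier == "svm":
        clf = SVC(kernel="rbf")
        clf.fit(x_tr, y_tr)
        pred = clf.predict(x_va)
    else:
        k = spec.k_neighbors
        if k >= len(x_tr):
            warnings.warn("fewer training samples than k; reducing k", stacklevel=3)
            k = max(len(x_tr) - 1, 1)
        pred = _knn_predict(x_tr, y_tr, x_va, k)
    return float(np.mean(pred != y_va))


def cv_error(x: np.ndarray, y: np.ndarray, mask: np.ndarray,
             spec: FitnessSpec | None = None, random_state: int = 0) -> float:
    """Stratified k-fold cross-validated error of the masked feature set.

    Features are min-max scaled with training-fold statistics only, so no
    information leaks from the validation fold.  Raises on an empty mask —
    the caller assigns the worst fitness instead of classifying nothing.
    """
    spec = spec or FitnessSpec()
    mask = np.asarray(mask, bool)
    if mask.sum() == 0:
        raise ValueError("empty feature mask")
    x_sel = np.asarray(x, float)[:, mask]
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=random_state)
    errs = []
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*least populated class.*")
        for tr, va in skf.split(x_sel, y):
            errs.append(_fold_error(x_sel[tr], y[tr], x_sel[va], y[va], spec))
    return float(np.mean(errs))


def make_fs_objective(x_train: np.ndarray, y_train: np.ndarray,
                      spec: FitnessSpec, cv_seed: int):
    """Position -> fitness objective with a per-mask cache.

    Many positions binarize to the same mask; caching the cross-validation
    error by mask keeps wrapper runs cheap without changing any result
    (fold assignment is fixed by ``cv_seed`` for the whole run).
    """
    n_features = x_train.shape[1]
    cache: dict[bytes, float] = {}
    counter = {"evals": 0}

    def objective(position: np.ndarray) -> float:
        mask = binarize(position, spec.threshold)
        key = np.packbits(mask).tobytes()
        if key not in cache:
            counter["evals"] += 1
            if mask.sum() == 0:
                cache[key] = 1.0
            else:
                err = cv_error(x_train, y_train, mask, spec, random_state=cv_seed)
                cache[key] = subset_fitness(err, int(mask.sum()), n_features, spec)
        return cache[key]

    objective.cache = cache
    objective.counter = counter
    return objective


def _holdout_accuracy(x_train, y_train, x_test, y_test, mask, spec) -> float:
    """Percent accuracy of the spec's classifier on the held-out split."""
    x_tr, x_te = x_train[:, mask], x_test[:, mask]
    err = _fold_error(x_tr, y_train, x_te, y_test, spec)
    return 100.0 * (1.0 - err)


def select_features(x: np.ndarray, y: np.ndarray, algorithm: str = "mswoa",
                    config: MSWOAConfig | None = None,
                    spec: FitnessSpec | None = None, seed: int = 0) -> FSResult:
    """End-to-end wrapper selection on a labeled feature matrix.

    The data are split 80/20 with stratification; the optimizer minimizes
    the subset fitness under cross-validation on the 80% partition; the
    winning mask is then scored once on the 20% partition.  Everything is
    driven by ``seed``, so equal seeds give identical results — and, across
    algorithms, identical splits (paired comparisons).
    """
    x = np.asarray(x, float)
    y = np.asarray(y)
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    spec = spec or FitnessSpec()
    cfg = config if config is not None else MSWOAConfig()
    d = x.shape[1]

    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=0.2, stratify=y, random_state=seed)
    objective = make_fs_objective(x_tr, y_tr, spec, cv_seed=seed)

    t0 = time.perf_counter()
    run_cfg = MSWOAConfig(n=cfg.n, max_iter=cfg.max_iter, gamma=cfg.gamma,
                          regroup_period=cfg.regroup_period,
                          bes_fraction=cfg.bes_fraction, b=cfg.b, seed=seed,
                          lb=cfg.lb, ub=cfg.ub)
    if algorithm == "mswoa":
        record = mswoa_run(objective, d, run_cfg)
    elif algorithm == "woa":
        record = woa_run(objective, d, n=cfg.n, max_iter=cfg.max_iter,
                         seed=seed, b=cfg.b, lb=cfg.lb, ub=cfg.ub)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    wall = time.perf_counter() - t0

    mask = binarize(record.best_position, spec.threshold)
    if mask.sum() == 0:  # only possible if every visited subset was empty
        raise RuntimeError("optimizer never visited a non-empty subset")
    err = cv_error(x_tr, y_tr, mask, spec, random_state=seed)
    test_acc = _holdout_accuracy(x_tr, y_tr, x_te, y_te, mask, spec)
    return FSResult(mask=mask, fitness=record.best_fitness,
                    history=list(record.history), test_accuracy=test_acc,
                    cv_accuracy=100.0 * (1.0 - err), n_selected=int(mask.sum()),
                    n_features=d, wall_time=wall, seed=seed,
                    n_evaluations=record.n_evaluations)
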