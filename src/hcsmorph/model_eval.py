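"""Final model training, jackknife (leave-one-out) evaluation and
independent-image prediction.

Scaling is always derived from training samples only; in the jackknife each
round re-fits its own scaler (and, under the default policy, re-runs the
gamma/C grid search) on the 29 retained samples, so the held-out image never
influences the model that predicts it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from ._fastsvm import fit_predict_precomputed
from .features.extract import FeatureTable, LABEL_NON

__all__ = ["TrainedModel", "EvaluationReport", "PredictionReport",
           "DEFAULT_GAMMA_GRID", "DEFAULT_COST_GRID",
           "train", "jackknife", "nested_jackknife", "predict_independent",
           "grid_search_rbf"]

log = logging.getLogger(__name__)

DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-7, 9))
DEFAULT_COST_GRID = tuple(2.0**e for e in range(-7, 9))


@dataclass
class TrainedModel:
    selected_features: list
    center: np.ndarray
    scale: np.ndarray
    gamma: float
    cost: float
    classifier: SVC
    classes: list
    training_manifest: dict = field(default_factory=dict)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        Z = X[self.selected_features].to_numpy(dtype=np.float64)
        return (Z - self.center) / self.scale


@dataclass
class EvaluationReport:
    scheme: str
    accuracy: float
    per_sample: pd.DataFrame  # index sample_id, columns true/predicted
    confusion: np.ndarray  # 2x2, rows = true, cols = predicted (sorted classes)
    classes: list


@dataclass
class PredictionReport:
    per_image: pd.DataFrame  # columns predicted/decision_value
    fraction_non_neuroinflammation: float


def _fit_scaler(Z: np.ndarray, feature_names: list) -> tuple[np.ndarray, np.ndarray, list]:
    center = Z.mean(axis=0)
    scale = Z.std(axis=0)
    keep = scale > 0
    if not keep.all():
        dropped = [feature_names[i] for i in np.flatnonzero(~keep)]
        log.warning("dropping zero-variance features: %s", dropped)
    return center, scale, [feature_names[i] for i in np.flatnonzero(keep)]


def train(table: FeatureTable, features: list, gamma: float, cost: float) -> TrainedModel:
    """Z-score the selected features on the training table and fit an RBF-SVM."""
    classes = sorted(table.labels.unique())
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, got {classes}")
    missing = [f for f in features if f not in table.X.columns]
    if missing:
        raise ValueError(f"unknown features: {missing}")
    Z = table.X[features].to_numpy(dtype=np.float64)
    center, scale, kept = _fit_scaler(Z, list(features))
    if not kept:
        raise ValueError("all selected features are constant")
    idx = [list(features).index(f) for f in kept]
    center, scale = center[idx], scale[idx]
    Zk = (Z[:, idx] - center) / scale
    clf = SVC(kernel="rbf", gamma=gamma, C=cost)
    clf.fit(Zk, table.labels.to_numpy())
    return TrainedModel(
        selected_features=kept, center=center, scale=scale,
        gamma=gamma, cost=cost, classifier=clf, classes=classes,
        training_manifest={"sample_ids": list(table.X.index),
                           "class_counts": table.class_counts})


def grid_search_rbf(Z: np.ndarray, y: np.ndarray,
                    gamma_grid=DEFAULT_GAMMA_GRID, cost_grid=DEFAULT_COST_GRID,
                    n_folds: int = 5) -> tuple[float, float, float]:
    """Pick (gamma, C) by stratified k-fold CV accuracy on scaled data.

    Deterministic: folds are dealt round-robin per class in index order and
    grid ties resolve to the first (gamma, C) in grid order.
    """
    n = len(y)
    n_folds = min(n_folds, n)
    fold_of = np.empty(n, dtype=int)
    pos = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        for i, s in enumerate(idx):
            fold_of[s] = (pos + i) % n_folds
        pos += len(idx)
    folds = [(np.flatnonzero(fold_of != f), np.flatnonzero(fold_of == f))
             for f in range(n_folds)]
    D = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    best = (-1.0, gamma_grid[0], cost_grid[0])
    for gamma in gamma_grid:
        K = np.exp(-gamma * D)
        for cost in cost_grid:
            correct = 0
            for tr, te in folds:
                if len(np.unique(y[tr])) < 2 or len(te) == 0:
                    continue
                pred = fit_predict_precomputed(K[np.ix_(tr, tr)], y[tr],
                                               K[np.ix_(te, tr)], cost)
                correct += int((pred == y[te]).sum())
            acc = correct / n
            if acc > best[0]:
                best = (acc, gamma, cost)
    return best[1], best[2], best[0]


def jackknife(table: FeatureTable, features: list, param_policy: str = "grid",
              gamma: float | None = None, cost: float | None = None,
              gamma_grid=None, cost_grid=None,
              inner_folds: int = 5) -> EvaluationReport:
    """Leave-one-out evaluation over the table.

    ``param_policy="grid"`` re-selects gamma/C inside every round by inner
    cross-validation on the retained samples (leakage-free);
    ``param_policy="fixed"`` uses the supplied gamma/cost in every round.
    """
    classes = sorted(table.labels.unique())
    for c in classes:
        if (table.labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    if param_policy == "fixed" and (gamma is None or cost is None):
        raise ValueError("fixed policy requires gamma and cost")
    gamma_grid = tuple(gamma_grid or DEFAULT_GAMMA_GRID)
    cost_grid = tuple(cost_grid or DEFAULT_COST_GRID)

    X = table.X[list(features)].to_numpy(dtype=np.float64)
    y_str = table.labels.to_numpy()
    n = len(y_str)
    preds = np.empty(n, dtype=object)
    for held in range(n):
        tr = np.concatenate([np.arange(held), np.arange(held + 1, n)])
        Ztr = X[tr]
        center = Ztr.mean(axis=0)
        scale = Ztr.std(axis=0)
        keep = scale > 0
        if not keep.any():
            # all features constant in this round: majority vote
            vals, counts = np.unique(y_str[tr], return_counts=True)
            preds[held] = vals[np.argmax(counts)]
            continue
        scale_k = scale[keep]
        Zk = (Ztr[:, keep] - center[keep]) / scale_k
        zt = (X[held][keep] - center[keep]) / scale_k
        if param_policy == "grid":
            y01 = (y_str[tr] == classes[-1]).astype(int)
            g, c, _ = grid_search_rbf(Zk, y01, gamma_grid, cost_grid, inner_folds)
        else:
            g, c = gamma, cost
        clf = SVC(kernel="rbf", gamma=g, C=c)
        clf.fit(Zk, y_str[tr])
        preds[held] = clf.predict(zt[None, :])[0]

    correct = (preds == y_str)
    per_sample = pd.DataFrame({"true": y_str, "predicted": preds},
                              index=table.X.index)
    confusion = np.zeros((2, 2), dtype=int)
    for i, ct in enumerate(classes):
        for j, cp in enumerate(classes):
            confusion[i, j] = int(((y_str == ct) & (preds == cp)).sum())
    return EvaluationReport(scheme="jackknife", accuracy=float(correct.mean()),
                            per_sample=per_sample, confusion=confusion,
                            classes=classes)


def nested_jackknife(table: FeatureTable, select_fn) -> EvaluationReport:
    """Leave-one-out evaluation with the whole selection pipeline re-run
    inside every round.

    ``select_fn(sub_table) -> (features, gamma, cost)`` receives only the 29
    retained samples, so neither feature selection nor parameter choice ever
    sees the held-out image.  This removes the selection bias that inflates
    the plain jackknife when features are chosen on the full table.
    """
    classes = sorted(table.labels.unique())
    n = len(table)
    preds = []
    for held in range(n):
        keep = [k for k in range(n) if k != held]
        sub = FeatureTable(table.X.iloc[keep].copy(),
                           table.labels.iloc[keep].copy(), table.descriptors)
        features, gamma, cost = select_fn(sub)
        model = train(sub, features, gamma, cost)
        z = model.transform(table.X.iloc[[held]])
        preds.append(model.classifier.predict(z)[0])
    preds = np.asarray(preds, dtype=object)
    y_str = table.labels.to_numpy()
    per_sample = pd.DataFrame({"true": y_str, "predicted": preds},
                              index=table.X.index)
    confusion = np.zeros((2, 2), dtype=int)
    for i, ct in enumerate(classes):
        for j, cp in enumerate(classes):
            confusion[i, j] = int(((y_str == ct) & (preds == cp)).sum())
    return EvaluationReport(scheme="nested_jackknife",
                            accuracy=float((preds == y_str).mean()),
                            per_sample=per_sample, confusion=confusion,
                            classes=classes)


def predict_independent(model: TrainedModel, table: FeatureTable) -> PredictionReport:
    """Predict independent images and report the fraction assigned to the
    non-neuroinflammation class (the treatment-effect readout)."""
    if len(table) == 0:
        raise ValueError("empty test table")
    Z = model.transform(table.X)
    preds = model.classifier.predict(Z)
    dec = model.classifier.decision_function(Z)
    per_image = pd.DataFrame({"predicted": preds, "decision_value": dec},
                             index=table.X.index)
    frac = float((preds == LABEL_NON).mean())
    return PredictionReport(per_image=per_image,
                            fraction_non_neuroinflammation=frac)
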