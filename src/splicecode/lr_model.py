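"""Elastic-net logistic splicing-code model on positional RBP features.

One affine map plus sigmoid predicts PSI from the exon x (RBP x category)
count matrix.  The loss is binary cross-entropy with *continuous* targets in
[0, 1] (PSI itself, not a binarized label) plus an elastic-net penalty on
the weights (alpha = 0.001, L1 ratio = 0.7, applied per-sample, bias
unpenalized).  Optimization is plain minibatch SGD (learning rate 0.005,
batch 256) with a proximal soft-threshold step for the L1 part, so
coefficients can reach exactly zero.  One independent model is trained per
cell type; interpretation averages coefficients over 10 folds x 5 runs.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cv_eval import make_folds  # noqa: F401  (re-exported convenience)


@dataclasses.dataclass
class LRConfig:
    alpha: float = 0.001
    l1_ratio: float = 0.7
    learning_rate: float = 0.005
    batch_size: int = 256
    epochs: int = 200
    runs_per_fold: int = 5
    val_fraction: float = 0.1
    patience: int = 10

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 <= self.l1_ratio <= 1:
            raise ValueError("l1_ratio must be in [0, 1]")


@dataclasses.dataclass
class LRModel:
    weights: np.ndarray
    bias: float
    feature_names: list

    def predict(self, X) -> np.ndarray:
        return predict_lr(self, X)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _bce(p, y, eps=1e-12):
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train_lr(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    config: LRConfig | None = None,
    seed: int = 0,
) -> LRModel:
    """Fit the affine+sigmoid model by minibatch SGD.

    Early stopping monitors BCE on a held-out 10% split of the training
    data (patience 10); the best-validation weights are returned.
    """
    config = config or LRConfig()
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(X).shape[1])
    ]
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("targets must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n, p = X.shape
    n_val = int(round(n * config.val_fraction)) if n >= 20 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]
    w = np.zeros(p)
    b = 0.0
    lr = config.learning_rate
    l1 = config.alpha * config.l1_ratio
    l2 = config.alpha * (1 - config.l1_ratio)
    best = (np.inf, w.copy(), b)
    stall = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(len(Xtr))
        for lo in range(0, len(Xtr), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            pb = _sigmoid(xb @ w + b)
            grad_z = (pb - yb) / len(idx)
            gw = xb.T @ grad_z + l2 * w
            gb = float(grad_z.sum())
            w -= lr * gw
            b -= lr * gb
            if l1 > 0:  # proximal soft-threshold for the L1 part
                w = np.sign(w) * np.maximum(np.abs(w) - lr * l1, 0.0)
        if n_val:
            val_loss = _bce(_sigmoid(Xval @ w + b), yval)
            if val_loss < best[0] - 1e-6:
                best = (val_loss, w.copy(), b)
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break
    if n_val and np.isfinite(best[0]):
        _, w, b = best
    return LRModel(weights=w, bias=float(b), feature_names=feature_names)


def predict_lr(model: LRModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Deterministic predictions strictly inside (0, 1)."""
    if isinstance(X, pd.DataFrame):
        if list(X.columns) != model.feature_names:
            raise ValueError("feature columns do not match training columns")
        X = X.to_numpy(dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != len(model.weights):
        raise ValueError("feature columns do not match training columns")
    eps = np.finfo(float).eps
    return np.clip(_sigmoid(X @ model.weights + model.bias), eps, 1 - eps)


def average_coefficients(
    models: Sequence[LRModel], feature_matrix: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Arithmetic mean of coefficients across fold x run models.

    When the feature matrix is given, each feature also gets its exon
    support count (number of exons with >=1 site), used by the coefficient
    comparison filters.
    """
    if not models:
        raise ValueError("no models to average")
    names = models[0].feature_names
    for m in models:
        if m.feature_names != names:
            raise ValueError("models do not share feature columns")
    coefs = np.mean([m.weights for m in models], axis=0)
    out = pd.DataFrame({"feature": names, "coef": coefs}).set_index("feature")
    out["bias"] = np.mean([m.bias for m in models])
    if feature_matrix is not None:
        support = (feature_matrix > 0).sum(axis=0)
        out["support"] = support.reindex(names).to_numpy()
    return out


def compare_models(
    tables: Mapping[str, pd.DataFrame],
    pair: tuple,
    min_support: int = 50,
    min_abs: float = 0.05,
    top_k: int = 10,
) -> pd.DataFrame:
    """Rank features by cell-type coefficient difference.

    Features must be supported by >= ``min_support`` exons and have
    |coefficient| >= ``min_abs`` in at least one of the given models; the
    top ``top_k`` by |coef_A - coef_B| are returned.
    """
    a, b = pair
    ta, tb = tables[a], tables[b]
    df = pd.DataFrame({"coef_a": ta["coef"], "coef_b": tb["coef"]})
    if "support" in ta.columns:
        df["support"] = ta["support"]
        df = df[df["support"] >= min_support]
    keep = (df["coef_a"].abs() >= min_abs) | (df["coef_b"].abs() >= min_abs)
    df = df[keep].copy()
    df["diff"] = (df["coef_a"] - df["coef_b"]).abs()
    return df.sort_values("diff", ascending=False).head(top_k)


def cross_validate_lr(
    fm: pd.DataFrame,
    targets: pd.Series,
    folds: pd.Series,
    config: LRConfig | None = None,
    seed: int = 0,
) -> tuple:
    """Train per fold x run; return (models dict, run-averaged predictions).

    ``folds`` maps exon_id -> fold label; predictions for each exon come
    from the fold where it was held out, averaged over ``runs_per_fold``
    independently seeded runs.
    """
    config = config or LRConfig()
    fm = fm.loc[targets.index]
    preds = pd.Series(np.nan, index=targets.index, dtype=float)
    models = {}
    rng = np.random.default_rng(seed)
    for fold in sorted(folds.unique()):
        test_ids = folds.index[folds == fold]
        test_ids = test_ids.intersection(targets.index)
        train_ids = targets.index.difference(test_ids)
        fold_preds = np.zeros(len(test_ids))
        for run in range(config.runs_per_fold):
            m = train_lr(
                fm.loc[train_ids], targets.loc[train_ids], config, seed=int(rng.integers(2**31))
            )
            models[(fold, run)] = m
            fold_preds += predict_lr(m, fm.loc[test_ids])
        preds.loc[test_ids] = fold_preds / config.runs_per_fold
    return models, preds
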