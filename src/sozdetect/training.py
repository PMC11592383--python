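"""Training protocol for the seizure classifier.

Stratified 80/20 train+validation / test split, 10-fold cross-validation on
the 80%, SMOTE rebalancing of the 1:4 seizure/non-seizure imbalance,
mini-batch gradient descent with adaptive moment estimation on binary
cross-entropy, early stopping on validation loss with best-weight
restoration, and sensitivity-based selection of the best fold.

Seizure windows are the minority class and missing one is the costly
error, so sensitivity is the primary selection metric throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from .io_formats import LabeledWindowSet
from .preprocess import (
    PreprocessConfig,
    binarize_labels,
    fit_column_stats,
    standardize_set,
)
from .cnn import ModelSpec, ModelWeights, backward, forward, init_weights, predict
from .evaluation import MetricsReport, confusion, metrics

__all__ = [
    "TrainConfig",
    "FoldResult",
    "TrainingError",
    "split_train_test",
    "smote",
    "train_one",
    "cross_validate",
    "select_best",
    "train_single",
    "run_protocol",
]


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 16
    min_delta: float = 1e-4  # smallest val-loss drop that counts as progress
    n_folds: int = 10
    test_fraction: float = 0.2
    smote_scope: str = "train_only"  # or "train_plus_val"
    k_neighbors: int = 5
    selection_metric: str = "sensitivity"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.smote_scope not in ("train_only", "train_plus_val"):
            raise ValueError(f"unknown smote_scope {self.smote_scope!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FoldResult:
    fold_index: int
    accuracy: float
    sensitivity: float
    specificity: float
    weights: ModelWeights
    epochs_run: int
    val_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        for v in (self.accuracy, self.sensitivity, self.specificity):
            if not (0.0 <= v <= 100.0) and not np.isnan(v):
                raise ValueError("fold metrics must lie in [0, 100]")


def split_train_test(
    ws: LabeledWindowSet, config: TrainConfig
) -> tuple[LabeledWindowSet, LabeledWindowSet]:
    """Stratified, seeded 80/20 split preserving the binary class ratio."""
    y = binarize_labels(ws.labels5)
    if len(np.unique(y)) < 2:
        raise ValueError("both seizure and non-seizure windows are required")
    idx_train, idx_test = train_test_split(
        np.arange(len(ws)),
        test_size=config.test_fraction,
        stratify=y,
        random_state=config.seed,
    )
    idx_train.sort()
    idx_test.sort()

    def subset(idx):
        sub = LabeledWindowSet(windows=ws.windows[idx], labels5=ws.labels5[idx])
        sub.labels_binary = y[idx]
        return sub

    return subset(idx_train), subset(idx_test)


def smote(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    seed: int | np.random.Generator = 0,
    return_parents: bool = False,
):
    """Synthetic minority oversampling: interpolate between minority rows.

    Each synthetic row is x_i + lambda (x_nn - x_i) for a random minority
    row x_i, one of its ``k_neighbors`` nearest minority neighbours x_nn,
    and lambda ~ U[0, 1].  Returns (X, y) with equal class counts; an
    already-balanced input is returned unchanged.  With
    ``return_parents=True`` the (parent index, neighbour index, lambda)
    triples of the synthetic rows are appended to the return tuple.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote expects exactly two classes")
    if counts[0] == counts[1]:
        return (X, y, []) if return_parents else (X, y)
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    X_min = X[y == minority]
    if len(X_min) <= k_neighbors:
        raise ValueError(
            f"minority class has {len(X_min)} rows; needs > k_neighbors="
            f"{k_neighbors}"
        )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    _, neighbor_idx = nn.kneighbors(X_min)  # column 0 is the row itself
    parents = []
    synth = np.empty((n_needed, X.shape[1]))
    for s in range(n_needed):
        i = int(rng.integers(len(X_min)))
        j = int(neighbor_idx[i, 1 + rng.integers(k_neighbors)])
        lam = float(rng.random())
        synth[s] = X_min[i] + lam * (X_min[j] - X_min[i])
        parents.append((i, j, lam))
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return (X_out, y_out, parents) if return_parents else (X_out, y_out)


class _Adam:
    """Adaptive moment estimation with the conventional decay constants."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _flatten_params(weights: ModelWeights) -> list[np.ndarray]:
    out = []
    for w, b in weights.conv:
        out.extend((w, b))
    for w, b in weights.dense:
        out.extend((w, b))
    return out


def _bce(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _val_metrics(weights, X, y, model_spec) -> MetricsReport | None:
    verdicts = predict(weights, X, threshold=model_spec.threshold, spec=model_spec)
    try:
        return metrics(confusion(verdicts, y))
    except ValueError:
        return None


def train_one(
    model_spec: ModelSpec,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    seed: int | None = None,
) -> tuple[ModelWeights, dict]:
    """Fit one model with early stopping; returns best weights and history.

    ``train_set``/``val_set`` are (standardized windows, binary labels).
    Early stopping monitors validation loss; the best epoch's weights are
    restored.  A non-finite loss aborts with :class:`TrainingError`.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    X_tr, y_tr = np.asarray(train_set[0], dtype=float), np.asarray(train_set[1])
    X_val, y_val = np.asarray(val_set[0], dtype=float), np.asarray(val_set[1])
    weights = init_weights(model_spec, seed=seed)
    opt = _Adam(lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": [], "val_accuracy": [],
               "val_sensitivity": [], "val_specificity": []}
    best_loss, best_weights, best_epoch = np.inf, weights.copy(), 0
    n = len(X_tr)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            probs, cache = forward(
                weights, X_tr[idx], spec=model_spec, training_mode=True,
                rng=rng, return_cache=True,
            )
            loss = _bce(probs, y_tr[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            conv_g, dense_g = backward(weights, cache, y_tr[idx], model_spec)
            opt.step(
                _flatten_params(weights),
                _flatten_params(ModelWeights(conv=conv_g, dense=dense_g)),
            )
            epoch_losses.append(loss)
        val_probs = forward(weights, X_val, spec=model_spec, training_mode=False)
        val_loss = _bce(val_probs, y_val)
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        report = _val_metrics(weights, X_val, y_val, model_spec)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(report.accuracy if report else np.nan)
        history["val_sensitivity"].append(report.sensitivity if report else np.nan)
        history["val_specificity"].append(report.specificity if report else np.nan)
        if val_loss < best_loss - config.min_delta:
            best_loss, best_weights, best_epoch = val_loss, weights.copy(), epoch
        elif epoch - best_epoch >= config.patience:
            break
    history["best_epoch"] = best_epoch
    history["epochs_run"] = len(history["train_loss"])
    return best_weights, history


def cross_validate(
    ws: LabeledWindowSet,
    config: TrainConfig,
    model_spec: ModelSpec | None = None,
    preprocess_config: PreprocessConfig | None = None,
) -> list[FoldResult]:
    """Stratified k-fold cross-validation of the classifier.

    With ``smote_scope="train_only"`` (default) rebalancing happens inside
    each fold's training portion, so validation metrics come from untouched
    rows.  ``"train_plus_val"`` rebalances the whole train+validation pool
    before folding, replicating protocols that apply SMOTE ahead of the
    split at the cost of synthetic neighbours leaking into validation.
    """
    model_spec = model_spec or ModelSpec()
    pp = preprocess_config or PreprocessConfig()
    y = (
        ws.labels_binary
        if ws.labels_binary is not None
        else binarize_labels(ws.labels5)
    )
    if pp.standardization == "per_column" and pp.column_mu is None:
        fit_column_stats(ws.windows, pp)
    X = standardize_set(ws.windows, pp)
    if config.smote_scope == "train_plus_val":
        X, y = smote(X, y, config.k_neighbors, seed=config.seed)
    skf = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    results = []
    for fold, (tr_idx, val_idx) in enumerate(skf.split(X, y)):
        X_tr, y_tr = X[tr_idx], y[tr_idx]
        if config.smote_scope == "train_only":
            X_tr, y_tr = smote(
                X_tr, y_tr, config.k_neighbors, seed=config.seed + fold
            )
        weights, history = train_one(
            model_spec, (X_tr, y_tr), (X[val_idx], y[val_idx]), config,
            seed=config.seed + fold,
        )
        best = history["best_epoch"]
        results.append(
            FoldResult(
                fold_index=fold,
                accuracy=history["val_accuracy"][best],
                sensitivity=history["val_sensitivity"][best],
                specificity=history["val_specificity"][best],
                weights=weights,
                epochs_run=history["epochs_run"],
                val_indices=val_idx,
            )
        )
    return results


def select_best(
    results: list[FoldResult], metric: str = "sensitivity"
) -> FoldResult:
    """Argmax fold by the selection metric; ties break on accuracy, then index."""
    if not results:
        raise ValueError("no fold results to select from")
    return max(
        results,
        key=lambda r: (getattr(r, metric), r.accuracy, -r.fold_index),
    )


def train_single(
    trainval: LabeledWindowSet,
    config: TrainConfig | None = None,
    model_spec: ModelSpec | None = None,
    preprocess_config: PreprocessConfig | None = None,
    val_fraction: float = 0.1,
) -> tuple[ModelWeights, dict]:
    """Fit one classifier without cross-validation.

    Splits off a stratified ``val_fraction`` for early stopping, rebalances
    the training portion with SMOTE, and trains to convergence.  Returns
    (best weights, history).
    """
    config = config or TrainConfig()
    model_spec = model_spec or ModelSpec()
    pp = preprocess_config or PreprocessConfig()
    y = (
        trainval.labels_binary
        if trainval.labels_binary is not None
        else binarize_labels(trainval.labels5)
    )
    if pp.standardization == "per_column" and pp.column_mu is None:
        fit_column_stats(trainval.windows, pp)
    X = standardize_set(trainval.windows, pp)
    tr_idx, val_idx = train_test_split(
        np.arange(len(X)), test_size=val_fraction, stratify=y,
        random_state=config.seed,
    )
    X_tr, y_tr = smote(X[tr_idx], y[tr_idx], config.k_neighbors, seed=config.seed)
    return train_one(model_spec, (X_tr, y_tr), (X[val_idx], y[val_idx]), config)


def run_protocol(
    ws: LabeledWindowSet,
    config: TrainConfig | None = None,
    model_spec: ModelSpec | None = None,
    preprocess_config: PreprocessConfig | None = None,
) -> dict:
    """The full protocol: split, cross-validate, select best fold, test.

    Returns a dict with the fold results, the selected fold, the held-out
    test metrics of the selected weights, and the preprocessing config used
    (with column statistics fitted on the training split if applicable).
    """
    config = config or TrainConfig()
    model_spec = model_spec or ModelSpec()
    pp = preprocess_config or PreprocessConfig()
    trainval, test = split_train_test(ws, config)
    if pp.standardization == "per_column":
        fit_column_stats(trainval.windows, pp)
    folds = cross_validate(trainval, config, model_spec, pp)
    best = select_best(folds, config.selection_metric)
    X_test = standardize_set(test.windows, pp)
    verdicts = predict(
        best.weights, X_test, threshold=model_spec.threshold, spec=model_spec
    )
    test_report = metrics(confusion(verdicts, test.labels_binary))
    return {
        "folds": folds,
        "best": best,
        "test_metrics": test_report,
        "preprocess_config": pp,
        "model_spec": model_spec,
        "config": config,
    }
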