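"""Shallow pattern-recognition network for sonogram classification.

A feed-forward network with tanh hidden layers (default two layers of
10 units) and a softmax output maps the spectral feature vector of a
whole sonogram to class posteriors.  Training minimises the mean
cross-entropy with scaled conjugate gradient (SCG) backpropagation —
Møller's algorithm, a batch conjugate-gradient method that sizes each
step from a Levenberg–Marquardt-regularised local quadratic model
instead of a line search.  A plain gradient-descent optimizer is
available behind a config switch for comparison.

Targets are one-hot rows (all zeros except a single 1 in the element
of the true class).  Feature normalisation statistics are estimated on
the training split and persisted with the model so that prediction
applies the identical affine map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .features import FeatureStats, FeatureVector, normalize_features

__all__ = [
    "LabeledDataset",
    "TrainingConfig",
    "NetworkModel",
    "EvaluationReport",
    "train",
    "predict",
    "evaluate",
    "save_model",
    "load_model",
    "TrainingError",
    "DivergenceError",
]


class TrainingError(ValueError):
    pass


class DivergenceError(RuntimeError):
    """Loss became non-finite during optimisation."""


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix plus one-hot targets.

    Each target row has exactly one 1; ``class_names[i]`` names the
    class encoded by a 1 in column i.
    """

    features: np.ndarray
    targets: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=np.float64)
        t = np.asarray(self.targets, dtype=np.float64)
        if f.ndim != 2 or t.ndim != 2 or f.shape[0] != t.shape[0]:
            raise ValueError("features and targets must be 2D with equal row count")
        if not np.all(np.isfinite(f)):
            raise ValueError("features contain non-finite values")
        if not (np.all((t == 0) | (t == 1)) and np.all(t.sum(axis=1) == 1)):
            raise ValueError("targets must be one-hot rows")
        if t.shape[1] != len(self.class_names):
            raise ValueError("class_names length must equal target width")
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "targets", t)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_classes(self) -> int:
        return self.targets.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return self.targets.argmax(axis=1)

    @classmethod
    def from_labels(
        cls,
        features: np.ndarray,
        labels: Sequence[int],
        class_names: Sequence[str],
    ) -> "LabeledDataset":
        labels = np.asarray(labels, dtype=int)
        t = np.zeros((labels.size, len(class_names)))
        t[np.arange(labels.size), labels] = 1.0
        return cls(features=features, targets=t, class_names=tuple(class_names))


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs for :func:`train`.

    hidden_sizes : default (10, 10) — two hidden layers of 10 units.
    max_epochs : SCG iteration budget (full-batch) per restart.
    val_fraction : stratified share held out for early stopping.
    patience : epochs of non-improving validation loss before stopping.
    optimizer : "scg" (default) or "gd" (plain gradient descent).
    learning_rate : used only by the "gd" fallback.
    regularization : L2 penalty weight on connection weights (not
        biases), added to the cross-entropy performance function.
        Essential when the feature dimension (384) far exceeds the
        sample count.
    n_restarts : independent weight initialisations; the restart with
        the lowest validation loss wins.  Shallow nets of this size
        land in poor local minima for a minority of inits, so a few
        seeded restarts stabilise the fit.
    """

    hidden_sizes: tuple[int, ...] = (10, 10)
    max_epochs: int = 400
    val_fraction: float = 0.15
    patience: int = 12
    optimizer: str = "scg"
    learning_rate: float = 0.05
    regularization: float = 0.01
    n_restarts: int = 5

    def __post_init__(self) -> None:
        if self.optimizer not in ("scg", "gd"):
            raise ValueError(f"optimizer must be 'scg' or 'gd', got {self.optimizer!r}")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden layer sizes must be >= 1")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class NetworkModel:
    """Trained network: weights, normalisation stats, training record."""

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_stats: FeatureStats
    class_names: tuple[str, ...]
    seed: int = 0
    training_loss: list[float] = field(default_factory=list)
    validation_loss: list[float] = field(default_factory=list)
    epochs_run: int = 0

    @property
    def input_dim(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_classes(self) -> int:
        return self.layer_sizes[-1]


# ---------------------------------------------------------------- forward

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(weights, biases, x):
    """Returns (activations per layer, output posteriors)."""
    acts = [x]
    a = x
    for w, b in zip(weights[:-1], biases[:-1]):
        a = np.tanh(a @ w + b)
        acts.append(a)
    out = _softmax(a @ weights[-1] + biases[-1])
    acts.append(out)
    return acts, out


def _cross_entropy(p: np.ndarray, t: np.ndarray) -> float:
    return float(-(t * np.log(np.clip(p, 1e-300, None))).sum() / p.shape[0])


def _loss_grad(weights, biases, x, t, reg: float = 0.0):
    """Regularised mean cross-entropy and its gradient (backprop).

    ``reg`` adds 0.5 * reg * sum(W**2) over connection weights only;
    the softmax + cross-entropy pairing gives the usual (p - t) output
    delta.
    """
    acts, p = _forward(weights, biases, x)
    n = x.shape[0]
    loss = _cross_entropy(p, t)
    delta = (p - t) / n
    gw, gb = [], []
    for i in range(len(weights) - 1, -1, -1):
        gw.insert(0, acts[i].T @ delta)
        gb.insert(0, delta.sum(axis=0))
        if i > 0:
            delta = (delta @ weights[i].T) * (1.0 - acts[i] ** 2)
    if reg > 0:
        for i, w in enumerate(weights):
            loss += 0.5 * reg * float((w * w).sum())
            gw[i] = gw[i] + reg * w
    return loss, gw, gb


def _pack(gw, gb):
    return np.concatenate([g.ravel() for g in gw] + [g.ravel() for g in gb])


def _unpack(vec, layer_sizes):
    weights, biases, i = [], [], 0
    for a, b in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(vec[i : i + a * b].reshape(a, b))
        i += a * b
    for b in layer_sizes[1:]:
        biases.append(vec[i : i + b])
        i += b
    return weights, biases


def _init_params(layer_sizes, rng):
    """Symmetric uniform init scaled by fan-in."""
    weights, biases = [], []
    for a, b in zip(layer_sizes[:-1], layer_sizes[1:]):
        bound = 1.0 / np.sqrt(a)
        weights.append(rng.uniform(-bound, bound, size=(a, b)))
        biases.append(np.zeros(b))
    return weights, biases


# ------------------------------------------------------------- optimizers

def _scg_minimize(fun_grad, w0, max_epochs, callback):
    """Møller's scaled conjugate gradient on a flat parameter vector.

    ``fun_grad(w) -> (loss, grad)``; ``callback(epoch, w, loss)`` may
    return True to request early stop.  Returns the final weights.
    """
    sigma0 = 1e-5
    lam, lam_bar = 1e-6, 0.0
    w = w0.copy()
    f_w, grad = fun_grad(w)
    if not np.isfinite(f_w):
        raise DivergenceError("non-finite loss at initialisation")
    r = -grad
    p = r.copy()
    success = True
    n_params = w.size
    delta = 0.0
    for epoch in range(1, max_epochs + 1):
        p_norm2 = float(p @ p)
        if success:
            if p_norm2 == 0.0:
                break
            sigma = sigma0 / np.sqrt(p_norm2)
            _, grad_sigma = fun_grad(w + sigma * p)
            s = (grad_sigma - grad) / sigma
            delta = float(p @ s)
        # Levenberg-Marquardt regularisation of the curvature estimate
        delta += (lam - lam_bar) * p_norm2
        if delta <= 0:  # make the Hessian model positive definite
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, grad_new = fun_grad(w + alpha * p)
        if not np.isfinite(f_new):
            raise DivergenceError(f"non-finite loss at epoch {epoch}")
        big_delta = 2.0 * delta * (f_w - f_new) / (mu * mu)
        if big_delta >= 0:  # successful step: accept
            w = w + alpha * p
            f_w = f_new
            r_new = -grad_new
            grad = grad_new
            lam_bar = 0.0
            success = True
            if epoch % n_params == 0:  # restart with steepest descent
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if big_delta >= 0.75:
                lam *= 0.25
        else:
            lam_bar = lam
            success = False
        if big_delta < 0.25:
            lam += delta * (1.0 - big_delta) / p_norm2
        if callback(epoch, w, f_w):
            break
        if float(r @ r) < 1e-18 or lam > 1e20:
            callback(epoch, w, f_w)
            break
    return w


def _gd_minimize(fun_grad, w0, max_epochs, lr, callback):
    w = w0.copy()
    for epoch in range(1, max_epochs + 1):
        loss, grad = fun_grad(w)
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite loss at epoch {epoch}")
        w = w - lr * grad
        if callback(epoch, w, loss):
            break
    return w


# ------------------------------------------------------------------ train

def _stratified_split(labels, val_fraction, rng):
    """Deterministic per-class shuffle; returns (train_idx, val_idx)."""
    train_idx, val_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        n_val = int(round(val_fraction * idx.size))
        if val_fraction > 0 and idx.size >= 2:
            n_val = max(n_val, 1)
        n_val = min(n_val, idx.size - 1)
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train(
    data: LabeledDataset,
    config: TrainingConfig | None = None,
    seed: int = 0,
) -> NetworkModel:
    """Train the pattern-recognition network; deterministic given seed.

    Features are z-scored with statistics from the training split; the
    best-validation-loss weights are kept, and training stops when the
    validation loss has not improved for ``config.patience`` epochs.
    """
    config = config or TrainingConfig()
    labels = data.labels
    counts = np.bincount(labels, minlength=data.n_classes)
    for c, n in enumerate(counts):
        if n == 0:
            raise TrainingError(f"class {data.class_names[c]!r} absent from dataset")
    if data.n_samples < data.n_classes:
        raise TrainingError("need at least one sample per class")

    rng = np.random.default_rng(seed)
    tr_idx, va_idx = _stratified_split(labels, config.val_fraction, rng)
    stats = FeatureStats.from_matrix(data.features[tr_idx])
    x_tr = normalize_features(data.features[tr_idx], stats)
    t_tr = data.targets[tr_idx]
    x_va = normalize_features(data.features[va_idx], stats) if va_idx.size else None
    t_va = data.targets[va_idx] if va_idx.size else None

    layer_sizes = (data.features.shape[1], *config.hidden_sizes, data.n_classes)

    def fun_grad(wvec):
        ws, bs = _unpack(wvec, layer_sizes)
        loss, gw, gb = _loss_grad(ws, bs, x_tr, t_tr, reg=config.regularization)
        return loss, _pack(gw, gb)

    best_overall = None  # (selection loss, train curve, val curve, weights)
    for _ in range(config.n_restarts):
        w_list, b_list = _init_params(layer_sizes, rng)
        w0 = _pack(w_list, b_list)
        train_losses: list[float] = []
        val_losses: list[float] = []
        state = {"best_val": np.inf, "best_w": w0.copy(), "bad": 0}

        def callback(epoch, wvec, loss):
            train_losses.append(loss)
            if x_va is None:
                state["best_w"] = wvec.copy()
                state["best_val"] = loss
                return False
            ws, bs = _unpack(wvec, layer_sizes)
            _, p = _forward(ws, bs, x_va)
            vloss = _cross_entropy(p, t_va)
            val_losses.append(vloss)
            if vloss < state["best_val"] - 1e-12:
                state["best_val"] = vloss
                state["best_w"] = wvec.copy()
                state["bad"] = 0
            else:
                state["bad"] += 1
            return state["bad"] >= config.patience

        if config.optimizer == "scg":
            _scg_minimize(fun_grad, w0, config.max_epochs, callback)
        else:
            _gd_minimize(
                fun_grad, w0, config.max_epochs, config.learning_rate, callback
            )
        if best_overall is None or state["best_val"] < best_overall[0]:
            best_overall = (
                state["best_val"], train_losses, val_losses, state["best_w"]
            )

    _, train_losses, val_losses, best_w = best_overall
    ws, bs = _unpack(best_w, layer_sizes)
    return NetworkModel(
        layer_sizes=layer_sizes,
        weights=[w.copy() for w in ws],
        biases=[b.copy() for b in bs],
        feature_stats=stats,
        class_names=data.class_names,
        seed=seed,
        training_loss=train_losses,
        validation_loss=val_losses,
        epochs_run=len(train_losses),
    )


# ---------------------------------------------------------------- predict

def predict(
    model: NetworkModel, f: Union[FeatureVector, np.ndarray]
) -> np.ndarray:
    """Class posterior(s) for one feature vector or a (n, d) matrix.

    Output rows lie on the probability simplex; argmax is the
    predicted class.
    """
    x = f.values if isinstance(f, FeatureVector) else np.asarray(f, dtype=np.float64)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.input_dim:
        raise ValueError(
            f"feature length {x.shape[1]} != model input_dim {model.input_dim}"
        )
    x = normalize_features(x, model.feature_stats)
    _, p = _forward(model.weights, model.biases, x)
    return p[0] if single else p


# --------------------------------------------------------------- evaluate

@dataclass(frozen=True)
class EvaluationReport:
    """Confusion matrix, per-class rates, accuracy and ROC/AUC."""

    confusion: np.ndarray  # [true, predicted] counts
    class_names: tuple[str, ...]
    accuracy: float
    per_class: dict  # class -> {tp_pct, fp_pct, tn_pct, fn_pct}
    roc: dict  # class -> {fpr: [...], tpr: [...], auc: float}
    auc: float  # binary: positive-class AUC; else macro one-vs-rest

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "roc": {
                k: {kk: (list(vv) if not np.isscalar(vv) else vv) for kk, vv in v.items()}
                for k, v in self.roc.items()
            },
            "auc": self.auc,
        }


def evaluate(model: NetworkModel, data: LabeledDataset) -> EvaluationReport:
    """Confusion matrix, per-class FN/FP/TP/TN percentages, ROC and AUC.

    AUC uses the trapezoidal rule over all score thresholds; binary
    problems report the positive-class (index 1) AUC, multiclass the
    one-vs-rest macro average.  Raises ``ValueError`` when only one
    class is present (AUC undefined).
    """
    labels = data.labels
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined: dataset contains a single class")
    scores = predict(model, data.features)
    pred = scores.argmax(axis=1)
    k = data.n_classes
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (labels, pred), 1)
    n = labels.size
    accuracy = float(np.trace(confusion) / n)

    per_class = {}
    roc = {}
    aucs = []
    for c, name in enumerate(data.class_names):
        tp = int(confusion[c, c])
        fn = int(confusion[c].sum() - tp)
        fp = int(confusion[:, c].sum() - tp)
        tn = n - tp - fn - fp
        per_class[name] = {
            "tp_pct": 100.0 * tp / n,
            "fp_pct": 100.0 * fp / n,
            "tn_pct": 100.0 * tn / n,
            "fn_pct": 100.0 * fn / n,
        }
        binary_true = (labels == c).astype(int)
        if binary_true.min() == binary_true.max():
            continue  # one-vs-rest degenerate for this class
        fpr, tpr, _ = _roc_curve(binary_true, scores[:, c])
        auc_c = float(_trapezoid_auc(fpr, tpr))
        roc[name] = {"fpr": fpr, "tpr": tpr, "auc": auc_c}
        aucs.append(auc_c)

    if k == 2 and data.class_names[1] in roc:
        overall_auc = roc[data.class_names[1]]["auc"]
    else:
        overall_auc = float(np.mean(aucs))
    return EvaluationReport(
        confusion=confusion,
        class_names=data.class_names,
        accuracy=accuracy,
        per_class=per_class,
        roc=roc,
        auc=overall_auc,
    )


def crossval_evaluate(
    data: LabeledDataset,
    config: TrainingConfig | None = None,
    seed: int = 0,
    n_folds: int = 5,
) -> dict:
    """Stratified K-fold held-out performance of the full training recipe.

    Every sample is scored exactly once by a network that never saw it,
    so the pooled accuracy/AUC estimate carries far less split noise
    than a single small test partition.  Deterministic given seed.
    """
    config = config or TrainingConfig()
    labels = data.labels
    rng = np.random.default_rng(seed)
    fold = np.empty(data.n_samples, dtype=int)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        fold[idx] = np.arange(idx.size) % n_folds
    scores = np.zeros((data.n_samples, data.n_classes))
    for k in range(n_folds):
        tr = fold != k
        dtr = LabeledDataset(
            data.features[tr], data.targets[tr], data.class_names
        )
        model = train(dtr, config, seed=int(rng.integers(0, 2**31 - 1)))
        scores[~tr] = predict(model, data.features[~tr])
    pred = scores.argmax(axis=1)
    accuracy = float((pred == labels).mean())
    if data.n_classes == 2:
        fpr, tpr, _ = _roc_curve(labels, scores[:, 1])
        auc_val = float(_trapezoid_auc(fpr, tpr))
    else:
        aucs = []
        for c in range(data.n_classes):
            fpr, tpr, _ = _roc_curve((labels == c).astype(int), scores[:, c])
            aucs.append(float(_trapezoid_auc(fpr, tpr)))
        auc_val = float(np.mean(aucs))
    return {"accuracy": accuracy, "auc": auc_val, "scores": scores, "folds": fold}


# ------------------------------------------------------------ persistence

def save_model(model: NetworkModel, path: Union[str, Path]) -> None:
    """Serialise to a single JSON file (documented schema)."""
    doc = {
        "layer_sizes": list(model.layer_sizes),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "feature_location": model.feature_stats.location.tolist(),
        "feature_scale": model.feature_stats.scale.tolist(),
        "class_names": list(model.class_names),
        "seed": model.seed,
        "training_loss": model.training_loss,
        "validation_loss": model.validation_loss,
        "epochs_run": model.epochs_run,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: Union[str, Path]) -> NetworkModel:
    doc = json.loads(Path(path).read_text())
    return NetworkModel(
        layer_sizes=tuple(doc["layer_sizes"]),
        weights=[np.asarray(w, dtype=np.float64) for w in doc["weights"]],
        biases=[np.asarray(b, dtype=np.float64) for b in doc["biases"]],
        feature_stats=FeatureStats(
            location=np.asarray(doc["feature_location"]),
            scale=np.asarray(doc["feature_scale"]),
        ),
        class_names=tuple(doc["class_names"]),
        seed=doc.get("seed", 0),
        training_loss=doc.get("training_loss", []),
        validation_loss=doc.get("validation_loss", []),
        epochs_run=doc.get("epochs_run", 0),
    )
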