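"""Transfer schemes, SGDM training with early stopping, SVM branch, and
evaluation.

Three transfer-learning schemes are supported on any backbone built from a
layer table:

* ``FE_CLASSIFIER`` — retrain everything with the new classification head;
* ``LAST3_CONV`` — freeze the first two convolutional layers (learning rate
  multiplier zero) and retrain the remaining convolutions plus the head;
* ``FE_SVM`` — freeze all weights and expose fc6 activation vectors for a
  multiclass linear SVM trained with k-fold cross-validation and a grid
  search over the penalty parameter C.

Training uses stochastic gradient descent with momentum and L2 weight decay;
validation runs at a fixed epoch frequency and early stopping halts after the
validation loss has failed to improve for ``patience`` consecutive validation
points.  A checkpoint of the weights is kept per completed epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC

from vineprep.tl_harness.network import Network

__all__ = [
    "TLScheme",
    "TrainConfig",
    "SVMConfig",
    "EarlyStopper",
    "FeatureExtractor",
    "TrainResult",
    "SVMResult",
    "EvalResult",
    "apply_scheme",
    "train",
    "svm_classify",
    "evaluate",
]


class TLScheme(Enum):
    FE_CLASSIFIER = "fecls"
    LAST3_CONV = "last3"
    FE_SVM = "fesvm"


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings (full-scale defaults)."""

    learning_rate: float = 1e-5
    momentum: float = 0.9
    weight_decay: float = 1e-1
    batch_size: int = 32
    patience: int = 10
    validation_frequency: int = 1  # in epochs
    max_epochs: int = 30
    seed: int = 0
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("learning_rate", "batch_size", "patience",
                     "validation_frequency", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("momentum and weight_decay must be non-negative")


@dataclass(frozen=True)
class SVMConfig:
    feature_layer: str = "fc6"
    folds: int = 10
    C_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


class EarlyStopper:
    """Stop when the validation loss fails to improve for ``patience``
    consecutive validation points."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.since_best = 0

    def update(self, val_loss: float) -> bool:
        """Record one validation point; returns True when training must stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.since_best = 0
        else:
            self.since_best += 1
        return self.since_best >= self.patience


@dataclass
class FeatureExtractor:
    """Frozen backbone exposed as an image -> activation-vector map."""

    network: Network
    layer_name: str = "fc6"

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.network.activations(x, self.layer_name)


def apply_scheme(network: Network, scheme: TLScheme):
    """Configure layer freezing for a transfer scheme.

    Returns the network (FE_CLASSIFIER, LAST3_CONV) or a
    :class:`FeatureExtractor` over fc6 (FE_SVM).
    """
    scheme = TLScheme(scheme)
    conv_names = network.conv_layer_names()
    if scheme is TLScheme.FE_CLASSIFIER:
        network.set_lr_mult([l.name for l in network.layers], 1.0)
        return network
    if scheme is TLScheme.LAST3_CONV:
        network.set_lr_mult([l.name for l in network.layers], 1.0)
        network.set_lr_mult(conv_names[:2], 0.0)
        return network
    if scheme is TLScheme.FE_SVM:
        network.set_lr_mult([l.name for l in network.layers], 0.0)
        return FeatureExtractor(network=network)
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass
class TrainResult:
    network: Network
    history: dict[str, list[float]]
    checkpoints: list[dict[str, np.ndarray]] = field(repr=False,
                                                     default_factory=list)
    stopped_early: bool = False


def _iterate_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train(
    network: Network,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
) -> TrainResult:
    """SGD-with-momentum training with per-epoch validation and checkpoints.

    ``train_set`` / ``val_set`` are ``(X, y)`` with X of shape N x H x W x 3
    (float, already scaled) and integer labels matching the network head.
    Frozen layers (learning-rate multiplier zero) are never touched, so their
    weights stay bit-identical.
    """
    Xtr, ytr = train_set
    Xva, yva = val_set
    if len(Xtr) == 0 or len(Xva) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(int(config.seed) & 0x7FFFFFFF)
    velocity: dict[str, np.ndarray] = {}
    stopper = EarlyStopper(config.patience)
    history: dict[str, list[float]] = {
        "epoch": [], "train_loss": [], "train_acc": [],
        "val_loss": [], "val_acc": [],
    }
    checkpoints: list[dict[str, np.ndarray]] = []
    ckpt_dir = Path(config.checkpoint_dir) if config.checkpoint_dir else None
    if ckpt_dir is not None:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    stopped_early = False

    for epoch in range(1, config.max_epochs + 1):
        losses, accs = [], []
        for batch in _iterate_batches(len(Xtr), config.batch_size, rng):
            loss, acc = network.loss_and_grads(Xtr[batch], ytr[batch],
                                               train=True)
            losses.append(loss)
            accs.append(acc)
            for layer in network.trainable_layers():
                if layer.lr_mult == 0.0:
                    continue
                lr = config.learning_rate * layer.lr_mult
                for p in layer.params():
                    key = f"{layer.name}.{p}"
                    w = getattr(layer, p)
                    g = getattr(layer, "d" + p) + config.weight_decay * w
                    v = velocity.get(key)
                    if v is None:
                        v = np.zeros_like(w)
                    v = config.momentum * v - lr * g
                    velocity[key] = v
                    setattr(layer, p, w + v)
        checkpoints.append(network.get_weights())
        if ckpt_dir is not None:
            np.savez(ckpt_dir / f"epoch_{epoch:03d}.npz",
                     **checkpoints[-1])
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(float(np.mean(accs)))
        if epoch % config.validation_frequency == 0:
            val_loss, val_acc = network.loss_and_grads(Xva, yva, train=False)
            history["val_loss"].append(val_loss)
            history["val_acc"].append(val_acc)
            if stopper.update(val_loss):
                stopped_early = True
                break
        else:
            history["val_loss"].append(np.nan)
            history["val_acc"].append(np.nan)
    return TrainResult(network=network, history=history,
                       checkpoints=checkpoints, stopped_early=stopped_early)


@dataclass
class SVMResult:
    classifier: object
    best_C: float
    fold_accuracies: np.ndarray
    mean_accuracy: float


def svm_classify(
    features: np.ndarray, labels: np.ndarray, config: SVMConfig = SVMConfig()
) -> SVMResult:
    """Multiclass linear SVM with k-fold CV and a grid search over C.

    Requires at least ``folds`` samples in every class.  Reports fold-wise
    and mean cross-validated accuracy at the selected C and returns the
    classifier refit on all data.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    present = np.flatnonzero(counts)
    if (counts[present] < config.folds).any():
        bad = present[counts[present] < config.folds]
        raise ValueError(
            f"classes {bad.tolist()} have fewer than {config.folds} samples"
        )
    cv = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=0)
    search = GridSearchCV(
        LinearSVC(dual="auto", max_iter=5000),
        {"C": list(config.C_grid)},
        cv=cv,
        scoring="accuracy",
    )
    search.fit(features, labels)
    best_C = float(search.best_params_["C"])
    folds = cross_val_score(
        LinearSVC(dual="auto", max_iter=5000, C=best_C),
        features, labels, cv=cv, scoring="accuracy",
    )
    return SVMResult(
        classifier=search.best_estimator_,
        best_C=best_C,
        fold_accuracies=folds,
        mean_accuracy=float(folds.mean()),
    )


@dataclass
class EvalResult:
    accuracy: float
    confusion_percent: np.ndarray  # rows = true class, normalized to 100
    group_accuracy: float | None = None  # majority vote per raw image


def _predict(model, X: np.ndarray) -> np.ndarray:
    if isinstance(model, Network):
        return model.predict_labels(X)
    if hasattr(model, "predict"):
        return np.asarray(model.predict(X))
    raise TypeError(f"cannot predict with {type(model)!r}")


def evaluate(
    model,
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int = 6,
    groups: np.ndarray | None = None,
) -> EvalResult:
    """Accuracy and row-normalized confusion matrix in percentages.

    With ``groups`` (one id per sample, e.g. the source raw image of each
    crop), also reports per-raw-image accuracy by majority vote over each
    group's predicted labels.
    """
    if len(X) == 0:
        raise ValueError("empty test set")
    y = np.asarray(y)
    pred = _predict(model, X)
    acc = float((pred == y).mean())
    conf = np.zeros((n_classes, n_classes))
    for t, p in zip(y, pred):
        conf[t, p] += 1
    row_sums = conf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        conf_pct = np.where(row_sums > 0, conf / row_sums * 100.0, 0.0)
    group_acc = None
    if groups is not None:
        groups = np.asarray(groups)
        hits = []
        for g in np.unique(groups):
            sel = groups == g
            votes = np.bincount(pred[sel], minlength=n_classes)
            true = np.bincount(y[sel]).argmax()
            hits.append(votes.argmax() == true)
        group_acc = float(np.mean(hits))
    return EvalResult(accuracy=acc, confusion_percent=conf_pct,
                      group_accuracy=group_acc)
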