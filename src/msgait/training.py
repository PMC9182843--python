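"""Joint training of all branches and the global head.

The composite objective is

    L_overall = alpha * L_local + beta * L_global,
    L_local   = sum_i alpha_i * CE(local head of branch i),

with categorical cross-entropy CE and the hyperparameters of the reference
setup: Adam at learning rate 0.001, batch size 32, up to 200 epochs, early
stopping after 50 epochs without validation-loss improvement, alpha = 0.99,
beta = 0.87, uniform per-branch weights alpha_i = 1/s.  Fisher statistics
are refreshed on every batch; the best-validation weights are restored at
the end.  Training is bit-reproducible given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .network import MultiScaleGaitNet
from .synthetic import LabeledDataset

logger = logging.getLogger("msgait")

_EPS = 1e-7


def cross_entropy(o: np.ndarray, o_hat: np.ndarray) -> float:
    """Categorical cross-entropy -sum(o_hat * ln o), batch-averaged.

    ``o`` holds predicted probabilities (clipped to [1e-7, 1 - 1e-7]),
    ``o_hat`` the one-hot truth.  1-D inputs are a single sample; 2-D inputs
    are a batch (rows are samples).
    """
    o = np.asarray(o, dtype=np.float64)
    o_hat = np.asarray(o_hat, dtype=np.float64)
    if o.shape != o_hat.shape:
        raise ValueError(f"shape mismatch: {o.shape} vs {o_hat.shape}")
    o = np.clip(o, _EPS, 1.0 - _EPS)
    ce = -(o_hat * np.log(o)).sum(axis=-1)
    return float(np.mean(ce))


def local_loss(
    per_scale_preds: Sequence[np.ndarray],
    labels_onehot: np.ndarray,
    alpha_i: Sequence[float],
) -> float:
    """Weighted sum of per-branch cross-entropies."""
    if len(per_scale_preds) != len(alpha_i):
        raise ValueError("one weight per branch required")
    return float(sum(a * cross_entropy(p, labels_onehot)
                     for a, p in zip(alpha_i, per_scale_preds)))


def overall_loss(local: float, global_: float,
                 alpha: float, beta: float) -> float:
    """Composite loss alpha*local + beta*global."""
    return alpha * local + beta * global_


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the reference setup)."""

    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 50
    alpha: float = 0.99
    beta: float = 0.87
    alpha_i: Optional[Tuple[float, ...]] = None  # None -> uniform 1/s
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.early_stop_patience) <= 0:
            raise ValueError("all sizes and rates must be positive")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class TrainHistory:
    """Per-epoch loss trajectory and validation accuracy."""

    local_loss: List[float] = field(default_factory=list)
    global_loss: List[float] = field(default_factory=list)
    overall_loss: List[float] = field(default_factory=list)
    val_accuracy: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    best_epoch: int = -1

    def n_epochs(self) -> int:
        return len(self.overall_loss)


class Adam:
    """Standard Adam over a flat dict of parameter arrays."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps)


def _stratified_split(labels: np.ndarray, fraction: float,
                      rng: np.random.Generator
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Indices of (train, held-out) with per-class proportional sampling."""
    hold, train = [], []
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        n_hold = max(1, int(round(fraction * len(idx))))
        hold.extend(idx[:n_hold])
        train.extend(idx[n_hold:])
    return np.sort(np.array(train)), np.sort(np.array(hold))


def train(
    dataset: LabeledDataset,
    model: MultiScaleGaitNet,
    config: TrainConfig,
) -> Tuple[MultiScaleGaitNet, TrainHistory]:
    """Fit the network on a gallery set with early stopping.

    A stratified ``val_fraction`` of the gallery is held out to monitor the
    overall validation loss; the best-validation parameters are restored
    before returning.
    """
    labels = dataset.labels
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("training requires at least 2 classes")
    if len(present) != model.n_classes or present.max() != len(present) - 1:
        missing = sorted(set(range(model.n_classes)) - set(present.tolist()))
        raise ValueError(
            f"classes {missing} absent from the training split")

    s = len(model.scales)
    alpha_i = tuple(config.alpha_i) if config.alpha_i else (1.0 / s,) * s
    if len(alpha_i) != s:
        raise ValueError(f"alpha_i must have {s} entries")

    rng = np.random.default_rng(config.seed)
    X = dataset.signals()
    tr_idx, val_idx = _stratified_split(labels, config.val_fraction, rng)
    X_tr, y_tr = X[tr_idx], labels[tr_idx]
    X_val, y_val = X[val_idx], labels[val_idx]

    opt = Adam(model.params, config.learning_rate)
    history = TrainHistory()
    best_val = np.inf
    best_state = model.state_dict()
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(X_tr))
        ep_local = ep_global = ep_overall = 0.0
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            bi = order[start:start + config.batch_size]
            losses, grads = model.loss_and_grads(
                X_tr[bi], y_tr[bi], config.alpha, config.beta, alpha_i,
                train=True, rng=rng)
            opt.step(model.params, grads)
            ep_local += losses["local"]
            ep_global += losses["global"]
            ep_overall += losses["overall"]
            n_batches += 1
        history.local_loss.append(ep_local / n_batches)
        history.global_loss.append(ep_global / n_batches)
        history.overall_loss.append(ep_overall / n_batches)

        val_losses, _ = model.loss_and_grads(
            X_val, y_val, config.alpha, config.beta, alpha_i,
            train=False, update_fisher=False)
        probs, _ = model.predict(X_val)
        val_acc = float(np.mean(probs.argmax(axis=1) == y_val))
        history.val_loss.append(val_losses["overall"])
        history.val_accuracy.append(val_acc)

        lam_top = {t: float(st["fw"].lambda_.max())
                   for t, st in model.fisher.items()}
        logger.info(
            "epoch %d: loss=%.4f (local %.4f, global %.4f) "
            "val_loss=%.4f val_acc=%.3f top-lambda=%s",
            epoch, history.overall_loss[-1], history.local_loss[-1],
            history.global_loss[-1], val_losses["overall"], val_acc, lam_top)

        if val_losses["overall"] < best_val - 1e-9:
            best_val = val_losses["overall"]
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                logger.info("early stop at epoch %d (best %d)",
                            epoch, history.best_epoch)
                break

    model.load_state_dict(best_state)
    return model, history
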