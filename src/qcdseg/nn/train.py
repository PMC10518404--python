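"""Adam optimiser, early stopping and the mini-batch training loop."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import softmax_cross_entropy
from .network import UNet

__all__ = ["Adam", "EarlyStopping", "train_network", "TrainingLog"]


class Adam:
    def __init__(self, net: UNet, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(l.params[n]) for l, n in net.parameters()]
        self.v = [np.zeros_like(l.params[n]) for l, n in net.parameters()]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for (l, name), m, v in zip(self.net.parameters(), self.m, self.v):
            g = l.grads[name]
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            l.params[name] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class EarlyStopping:
    """Track the best validation loss; signal a stop after ``patience``
    consecutive epochs without improvement.  The best epoch's parameters are
    snapshotted so training can restore them afterwards."""

    def __init__(self, patience: int = 10, min_delta: float = 0.0) -> None:
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best_loss = np.inf
        self.best_state: dict | None = None
        self.best_epoch = -1
        self.bad_epochs = 0

    def update(self, epoch: int, val_loss: float, net: UNet) -> bool:
        """Record this epoch; return True when training should stop."""
        if val_loss < self.best_loss - self.min_delta:
            self.best_loss = val_loss
            self.best_state = net.get_state()
            self.best_epoch = epoch
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience

    def restore(self, net: UNet) -> None:
        if self.best_state is not None:
            net.set_state(self.best_state)


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    epochs_run: int = 0


def _eval_loss(net: UNet, x: np.ndarray, y: np.ndarray,
               batch_size: int) -> float:
    losses, weights = [], []
    for i in range(0, len(x), batch_size):
        logits = net.forward(x[i:i + batch_size], train=False)
        loss, _ = softmax_cross_entropy(logits, y[i:i + batch_size])
        losses.append(loss)
        weights.append(len(x[i:i + batch_size]))
    return float(np.average(losses, weights=weights))


def train_network(net: UNet, x_train: np.ndarray, y_train: np.ndarray,
                  x_val: np.ndarray, y_val: np.ndarray, *,
                  lr: float, max_epochs: int, patience: int,
                  batch_size: int = 8, seed: int = 0) -> TrainingLog:
    """Mini-batch Adam training with validation-loss early stopping.

    On return the network holds the parameters of the best validation epoch.
    Raises ``RuntimeError`` on a non-finite training loss.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(net, lr=lr)
    stopper = EarlyStopping(patience=patience)
    log = TrainingLog()
    for epoch in range(max_epochs):
        order = rng.permutation(len(x_train))
        epoch_losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            logits = net.forward(x_train[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {i // batch_size}"
                )
            net.backward(dlogits.astype(np.float32))
            opt.step()
            epoch_losses.append(loss)
        log.train_loss.append(float(np.mean(epoch_losses)))
        vloss = _eval_loss(net, x_val, y_val, batch_size)
        log.val_loss.append(vloss)
        log.epochs_run = epoch + 1
        if stopper.update(epoch, vloss, net):
            break
    stopper.restore(net)
    log.best_epoch = stopper.best_epoch
    return log
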