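"""Adam optimizer, losses and the mini-batch training loop."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .layers import Sequential

__all__ = ["Adam", "mse_loss", "gaussian_nll_loss", "TrainConfig",
           "TrainingHistory", "fit_network"]


class Adam:
    """Stochastic Adam with the standard defaults (b1=0.9, b2=0.999)."""

    def __init__(self, params: list[np.ndarray], learning_rate: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. the prediction."""
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


def gaussian_nll_loss(raw: np.ndarray, truth: np.ndarray, mu: np.ndarray,
                      sigma_floor: float = 1e-6):
    """Mean Gaussian negative log-likelihood with a rectified sigma head.

    ``sigma = relu(raw) + floor``; the mean ``mu`` is fixed (the output of
    the reconstruction method under study), only sigma is learned.  Returns
    the loss and its gradient w.r.t. the raw (pre-rectifier) output.

    The rectifier gradient is passed through on the active side and, on the
    dead side, only when it would push the output back up (``dL/dsigma <
    0``): a rectified sigma at the floor makes the likelihood term explode
    with no gradient path to recover, so dead head units must be able to
    climb out.
    """
    sigma = np.maximum(raw, 0.0) + sigma_floor
    resid2 = (truth - mu) ** 2
    loss = float(np.mean(resid2 / (2.0 * sigma ** 2) + np.log(sigma)))
    dsigma = (-resid2 / sigma ** 3 + 1.0 / sigma) / raw.size
    return loss, dsigma * ((raw > 0) | (dsigma < 0))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings shared by all network training in the package.

    Defaults follow the full-scale protocol (Adam at 1e-4, MSE, batch 64,
    up to 1000 epochs with early stopping on a 10% validation split);
    scaled-down runs override epochs/learning rate.
    """

    learning_rate: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 1000
    patience: int = 20
    val_fraction: float = 0.1
    sigma_floor: float = 1e-6
    #: global gradient-norm ceiling; NLL gradients blow up near the sigma
    #: floor and a single unclipped spike poisons Adam's moment estimates
    clip_norm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf


def fit_network(model: Sequential, X: np.ndarray, y: np.ndarray,
                config: TrainConfig, loss: str = "mse",
                mu: np.ndarray | None = None) -> TrainingHistory:
    """Mini-batch training with early stopping and best-weight restoration.

    ``X``/``y`` are stacks of input/target patches.  For ``loss='nll'`` the
    per-patch fixed means ``mu`` must be supplied and ``y`` holds the ground
    truth.  The best validation weights seen are restored on exit; with
    ``max_epochs == 0`` the model is left at initialization.
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    if loss not in ("mse", "nll"):
        raise ValueError("loss must be 'mse' or 'nll'")
    if loss == "nll" and mu is None:
        raise ValueError("loss='nll' requires fixed means mu")

    rng = np.random.default_rng(config.seed)
    n = len(X)
    n_val = max(1, int(round(config.val_fraction * n))) if n > 1 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:
        tr_idx = val_idx

    def evaluate(idx: np.ndarray) -> float:
        total = 0.0
        for start in range(0, idx.size, config.batch_size):
            sel = idx[start:start + config.batch_size]
            pred = model.forward(X[sel])
            if loss == "mse":
                val, _ = mse_loss(pred, y[sel])
            else:
                val, _ = gaussian_nll_loss(pred, y[sel], mu[sel],
                                           config.sigma_floor)
            total += val * sel.size
        return total / max(idx.size, 1)

    history = TrainingHistory()
    best_weights = model.get_weights()
    opt = Adam(model.params, config.learning_rate)
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(tr_idx)
        running = 0.0
        for start in range(0, order.size, config.batch_size):
            sel = order[start:start + config.batch_size]
            pred = model.forward(X[sel])
            if loss == "mse":
                val, grad = mse_loss(pred, y[sel])
            else:
                val, grad = gaussian_nll_loss(pred, y[sel], mu[sel],
                                              config.sigma_floor)
            model.zero_grads()
            model.backward(grad)
            grads = model.grads
            gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if config.clip_norm and gnorm > config.clip_norm:
                grads = [g * (config.clip_norm / gnorm) for g in grads]
            opt.step(grads)
            running += val * sel.size
        history.train_loss.append(running / order.size)
        vloss = evaluate(val_idx) if n_val else history.train_loss[-1]
        history.val_loss.append(vloss)
        if vloss < history.best_val_loss - 1e-12:
            history.best_val_loss = vloss
            history.best_epoch = epoch
            best_weights = model.get_weights()
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break
    if history.best_epoch >= 0:
        model.set_weights(best_weights)
    elif config.max_epochs > 0:  # pragma: no cover - degenerate
        warnings.warn("validation loss never improved; keeping final weights")
    return history
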