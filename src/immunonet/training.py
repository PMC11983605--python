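"""Supervised training: cross-entropy + L2, Adam / SGD-momentum, Xavier init,
seeded mini-batching and early stopping on validation loss.

The objective is

    J(θ) = cross_entropy + λ · Σ w²      (weights only, biases exempt)

minimized over seeded shuffled mini-batches.  Validation loss is recorded
once per epoch; when it fails to improve for ``patience`` consecutive epochs
training stops and the parameters of the best validation epoch are restored.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from ._autograd import Tensor
from .model import ModelConfig, ModelState, forward, param_specs
from .preprocess import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["Hyperparams", "TrainState", "cross_entropy", "initialize", "train"]


@dataclasses.dataclass(frozen=True)
class Hyperparams:
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 100
    dropout: float = 0.5            # applied by the model config; kept here for manifests
    l2: float = 0.0001
    optimizer: str = "adam"         # adam | sgd_momentum
    momentum: float = 0.9
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.l2 < 0:
            raise ValueError("l2 must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.optimizer not in ("adam", "sgd_momentum"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclasses.dataclass
class TrainState:
    model: ModelState
    train_loss: list[float]
    val_loss: list[float]
    best_epoch: int
    best_val_loss: float
    stopped_early: bool


def cross_entropy(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean −log p(true class) in nats over a batch of probability rows.

    Zero probability at the true class is clamped at 1e-12 with a warning
    rather than propagating −inf.
    """
    P = np.atleast_2d(np.asarray(probabilities, dtype=float))
    y = np.asarray(labels, dtype=int)
    if y.min(initial=0) < 0 or y.max(initial=0) >= P.shape[1]:
        raise ValueError("labels out of range for probability rows")
    p_true = P[np.arange(P.shape[0]), y]
    if (p_true <= 0).any():
        warnings.warn("zero probability at the true class; clamped at 1e-12")
        p_true = np.clip(p_true, 1e-12, None)
    return float(-np.mean(np.log(p_true)))


def initialize(config: ModelConfig, seed: int | None = None) -> ModelState:
    """Xavier-uniform weights (bound √(6/(fan_in+fan_out))), zero biases."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    for name, shape, fan_in, fan_out in param_specs(config):
        if ".b" in name:
            params[name] = np.zeros(shape)
        else:
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            params[name] = rng.uniform(-bound, bound, size=shape)
    return ModelState(config=config, params=params, init_seed=seed)


class _Adam:
    def __init__(self, params, hp: Hyperparams):
        self.hp = hp
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        hp = self.hp
        self.t += 1
        b1t = 1.0 - hp.beta1 ** self.t
        b2t = 1.0 - hp.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = hp.beta1 * self.m[k] + (1 - hp.beta1) * g
            self.v[k] = hp.beta2 * self.v[k] + (1 - hp.beta2) * g * g
            params[k] -= hp.learning_rate * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + hp.eps
            )


class _SGDMomentum:
    def __init__(self, params, hp: Hyperparams):
        self.hp = hp
        self.vel = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        for k, g in grads.items():
            self.vel[k] = self.hp.momentum * self.vel[k] - self.hp.learning_rate * g
            params[k] += self.vel[k]


def _full_loss(state: ModelState, X: np.ndarray, y: np.ndarray, batch: int = 2048) -> float:
    """Cross-entropy over a dataset with dropout off (no L2 term)."""
    total, n = 0.0, X.shape[0]
    params = {k: Tensor(v) for k, v in state.params.items()}
    for s in range(0, n, batch):
        logits = forward(params, state.config, X[s : s + batch])
        loss = logits.softmax_cross_entropy(y[s : s + batch])
        total += float(loss.data) * min(batch, n - s)
    return total / n


def train(
    config: ModelConfig,
    state0: ModelState,
    data: tuple[FeatureMatrix, FeatureMatrix],
    hp: Hyperparams,
) -> TrainState:
    """Run the training loop and return the best-validation-epoch model.

    ``data`` is the (train, validation) pair of feature matrices; the
    configured dropout is active on training batches only.
    """
    tr, va = data
    if tr.X.shape[1] != va.X.shape[1]:
        raise ValueError("train/validation feature dimensions differ")
    state = state0.copy()
    cfg = config
    rng = np.random.default_rng(hp.seed)
    opt = (_Adam if hp.optimizer == "adam" else _SGDMomentum)(state.params, hp)
    weight_keys = [k for k in state.params if ".b" not in k]

    train_hist: list[float] = []
    val_hist: list[float] = []
    best_val = np.inf
    best_epoch = -1
    best_params = {k: v.copy() for k, v in state.params.items()}
    stopped_early = False
    n = tr.X.shape[0]

    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            params = {k: Tensor(v, requires_grad=True) for k, v in state.params.items()}
            logits = forward(params, cfg, tr.X[idx], rng=rng)
            loss = logits.softmax_cross_entropy(tr.y[idx])
            if hp.l2 > 0:
                reg = params[weight_keys[0]].sum_squares()
                for k in weight_keys[1:]:
                    reg = reg + params[k].sum_squares()
                loss = loss + reg.scale(hp.l2)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // hp.batch_size}"
                )
            loss.backward()
            grads = {k: params[k].grad for k in params}
            opt.step(state.params, grads)
            epoch_loss += float(loss.data) * idx.size
            seen += idx.size
        train_hist.append(epoch_loss / max(seen, 1))
        vl = _full_loss(state, va.X, va.y)
        val_hist.append(vl)
        logger.info("epoch %d train_loss %.4f val_loss %.4f", epoch, train_hist[-1], vl)
        if vl < best_val - 1e-12:
            best_val = vl
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in state.params.items()}
        elif epoch - best_epoch >= hp.patience:
            stopped_early = True
            break

    if best_epoch >= 0:
        state.params = best_params
    return TrainState(
        model=state,
        train_loss=train_hist,
        val_loss=val_hist,
        best_epoch=best_epoch,
        best_val_loss=float(best_val) if best_epoch >= 0 else np.nan,
        stopped_early=stopped_early,
    )
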