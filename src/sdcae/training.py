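"""Joint supervised training of the autoencoder models.

The supervised autoencoder minimizes a weighted sum of two losses in a
single training run: the binary cross-entropy classification loss CL over
the predicted seizure probabilities, and the mean-squared reconstruction
loss RL between each input segment and its decoded reconstruction,

    TL = w_c * CL + w_r * RL,      defaults w_c = 0.5, w_r = 1.0.

Plain CNN variants have no decoder and train on CL alone.  Optimization
is Adam (learning rate 1e-4 at full scale) over shuffled mini-batches of
32 for a fixed number of epochs, with no early stopping or schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.functional import ShapeError
from .nn.models import SeizureNet
from .types import SdcaeError

__all__ = [
    "TrainingConfig",
    "TrainHistory",
    "TrainingError",
    "classification_loss",
    "classification_loss_grad",
    "reconstruction_loss",
    "reconstruction_loss_grad",
    "total_loss",
    "Adam",
    "train_model",
]


class TrainingError(SdcaeError, RuntimeError):
    """Training diverged (non-finite loss)."""


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters; defaults are the full-scale protocol."""

    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-4
    w_c: float = 0.5
    w_r: float = 1.0
    seed: int = 0
    prob_clip_eps: float = 1e-7
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-7

    def __post_init__(self) -> None:
        if not (0 < self.w_c <= 1) or not (0 < self.w_r <= 1):
            raise ValueError("loss weights w_c, w_r must lie in (0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch curves; reconstruction entries stay empty for DCNN variants."""

    train_accuracy: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    cl: list[float] = field(default_factory=list)
    rl: list[float] = field(default_factory=list)
    tl: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tl)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _clip(p: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def classification_loss(y_true: np.ndarray, y_pred: np.ndarray, eps: float = 1e-7) -> float:
    """Binary cross-entropy, mean over the batch; predictions clipped to
    [eps, 1-eps] for numerical stability."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ShapeError(f"label/prediction length mismatch: {y_true.shape} vs {y_pred.shape}")
    p = _clip(y_pred, eps)
    return float(-np.mean(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p)))


def classification_loss_grad(y_true: np.ndarray, y_pred: np.ndarray, eps: float = 1e-7) -> np.ndarray:
    """d CL / d y_pred; zero where the clip is active."""
    y_true = np.asarray(y_true, dtype=np.float64)
    p = _clip(y_pred, eps)
    g = -(y_true / p - (1.0 - y_true) / (1.0 - p)) / y_true.size
    return np.where((y_pred > eps) & (y_pred < 1.0 - eps), g, 0.0)


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean over segments of the per-segment mean squared error."""
    if x.shape != x_hat.shape:
        raise ShapeError(f"reconstruction shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def reconstruction_loss_grad(x: np.ndarray, x_hat: np.ndarray) -> np.ndarray:
    return 2.0 * (x_hat - x) / x.size


def total_loss(cl: float, rl: float, config: TrainingConfig | None = None) -> float:
    """TL = w_c * CL + w_r * RL."""
    cfg = config or TrainingConfig()
    return cfg.w_c * cl + cfg.w_r * rl


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with bias-corrected first/second moments."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def batch_losses_and_grads(model: SeizureNet, xb: np.ndarray, yb: np.ndarray,
                           config: TrainingConfig, train: bool = True):
    """One forward pass: losses plus the output gradients of TL.

    Returns ``(cl, rl, tl, prob, dprob, drecon)``; ``rl``/``drecon`` are
    0/None for decoder-free variants, in which case TL reduces to CL alone.
    """
    prob, recon = model.forward(xb, train=train)
    cl = classification_loss(yb, prob, config.prob_clip_eps)
    dcl = classification_loss_grad(yb, prob, config.prob_clip_eps)
    if recon is None:
        return cl, 0.0, cl, prob, dcl, None
    rl = reconstruction_loss(xb, recon)
    tl = total_loss(cl, rl, config)
    dprob = config.w_c * dcl
    drecon = config.w_r * reconstruction_loss_grad(xb, recon)
    return cl, rl, tl, prob, dprob, drecon


def train_model(
    model: SeizureNet,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
) -> TrainHistory:
    """Train in place for ``config.epochs`` epochs; returns per-epoch history.

    Mini-batches of ``config.batch_size`` are drawn from a fresh seeded
    shuffle each epoch.  DCAE variants descend TL, DCNN variants CL.  A
    non-finite loss aborts with :class:`TrainingError` naming the epoch.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2, eps=config.adam_eps)
    n = X.shape[0]
    history = TrainHistory()
    is_dcae = model.decoder is not None

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_cl = epoch_rl = epoch_tl = 0.0
        n_correct = 0
        n_batches = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo: lo + config.batch_size]
            xb, yb = X[idx], y[idx]
            model.zero_grads()
            cl, rl, tl, prob, dprob, drecon = batch_losses_and_grads(model, xb, yb, config)
            if not np.isfinite(tl):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            model.backward(dprob, drecon)
            opt.step()
            epoch_cl += cl
            epoch_rl += rl
            epoch_tl += tl
            n_correct += int(np.sum((prob >= 0.5) == (yb == 1)))
            n_batches += 1

        history.cl.append(epoch_cl / n_batches)
        history.tl.append(epoch_tl / n_batches)
        if is_dcae:
            history.rl.append(epoch_rl / n_batches)
        history.train_accuracy.append(n_correct / n)
        if X_test is not None and y_test is not None:
            prob_test = model.predict_proba(X_test)
            history.test_accuracy.append(float(np.mean((prob_test >= 0.5) == (y_test == 1))))
    return history
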