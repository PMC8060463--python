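"""Desk-scale benchmark runs used by the acceptance checks and examples.

Full-scale training (200 epochs, 32/32/64/64 filters, ten folds, twelve
model combinations) is a cluster-sized job; these helpers pin down a
reproducible scaled-down study that a laptop CPU finishes in minutes:
filter counts divided by 8, 30 epochs, a 400-segment balanced synthetic
cohort at 2 s segments, one held-out stratified fold.  The numbers it
produces are sanity surfaces for the implementation, not estimates of the
published full-scale benchmark.
"""

from __future__ import annotations

import numpy as np

from .dataset import SegmentDataset, build_dataset
from .evaluation import compute_metrics, confusion_from_probs
from .nn.models import ModelConfig, build_model
from .synth import make_toy_cohort
from .training import TrainingConfig, train_model

__all__ = ["scaled_dataset", "eval_reconstruction_loss", "scaled_learning_run"]

SCALED_DURATION_S = 2
SCALED_FILTER_DIVISOR = 8
SCALED_EPOCHS = 30
SCALED_LEARNING_RATE = 1e-3
SCALED_SEGMENTS = 400


def scaled_dataset(seed: int = 1) -> SegmentDataset:
    """400-segment balanced 2 s dataset from a 4-subject toy cohort."""
    cohort = make_toy_cohort(n_subjects=4, seizures_per_subject=4, seed=seed)
    ds = build_dataset(cohort, duration_s=SCALED_DURATION_S, seed=seed)
    per_class = SCALED_SEGMENTS // 2
    rng = np.random.default_rng(seed)
    keep = np.concatenate([
        rng.choice(np.where(ds.y == c)[0], size=per_class, replace=False)
        for c in (1, 0)
    ])
    keep.sort()
    return SegmentDataset(
        X=ds.X[keep], y=ds.y[keep], norm=ds.norm,
        subject_ids=[ds.subject_ids[i] for i in keep],
        start_s=ds.start_s[keep], fold_of=ds.fold_of[keep],
    )


def eval_reconstruction_loss(model, X: np.ndarray, batch_size: int = 64) -> float:
    """Inference-mode mean squared reconstruction error over a whole array."""
    total = 0.0
    for lo in range(0, len(X), batch_size):
        _, recon = model.forward(X[lo: lo + batch_size], train=False)
        total += float(((X[lo: lo + batch_size] - recon) ** 2).sum())
    return total / X.size


def scaled_learning_run(seed: int = 1, variant: str = "DCAE_BiLSTM",
                        ds: SegmentDataset | None = None) -> dict:
    """Train one desk-scale model with fold 0 held out; return its scores.

    Returns held-out accuracy (percent), the inference-mode reconstruction
    loss before and after training (NaN for decoder-free variants), the
    fractional RL reduction, and the problem size.
    """
    if ds is None:
        ds = scaled_dataset(seed)
    test = ds.fold_of == 0
    X_tr, y_tr = ds.X[~test], ds.y[~test]
    config = ModelConfig(variant, duration_s=SCALED_DURATION_S).tiny(SCALED_FILTER_DIVISOR)
    model = build_model(config, seed=seed)
    rl_init = eval_reconstruction_loss(model, X_tr) if model.decoder is not None else float("nan")
    tc = TrainingConfig(epochs=SCALED_EPOCHS, batch_size=32,
                        learning_rate=SCALED_LEARNING_RATE, seed=seed)
    history = train_model(model, X_tr, y_tr, tc)
    rl_final = eval_reconstruction_loss(model, X_tr) if model.decoder is not None else float("nan")
    prob = model.predict_proba(ds.X[test])
    metrics = compute_metrics(confusion_from_probs(ds.y[test], prob))
    return {
        "variant": variant,
        "held_out_accuracy_pct": metrics.accuracy,
        "rl_init": rl_init,
        "rl_final": rl_final,
        "rl_reduction": 1.0 - rl_final / rl_init if np.isfinite(rl_init) else float("nan"),
        "final_train_accuracy": history.train_accuracy[-1],
        "n_train": int(len(y_tr)),
        "n_test": int(test.sum()),
    }
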