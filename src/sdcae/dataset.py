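"""From annotated recordings to the balanced, normalized segment dataset.

The models classify fixed-length, non-overlapping multichannel windows
("segments") of 1, 2 or 4 s.  Ictal segments tile each seizure interval
from its onset; interictal candidates tile the seizure-free remainder of
the recording and are randomly downsampled so both classes have equal
count K.  The pooled 2K segments are then standardized with one global
z-score (single mean and standard deviation over every value of every
channel and segment), rescaled to [0, 1] with one global min–max, padded
from 23 to 24 channel columns so the width survives the encoder's
halvings, and assigned to stratified cross-validation folds.

Note the normalization is deliberately computed over the *whole* assembled
dataset before fold splitting, reproducing the original protocol; a
leakage-free alternative that fits the statistics on training folds only
is available via :func:`normalize_dataset` applied per split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .types import AnnotationSet, Recording, SdcaeError, SeizureInterval, ValidationError

__all__ = [
    "Segment",
    "NormalizationParams",
    "SegmentDataset",
    "ImbalanceError",
    "StratificationError",
    "DegenerateDataError",
    "extract_segments",
    "balance_dataset",
    "normalize_dataset",
    "pad_channel_dim",
    "assign_stratified_folds",
    "build_dataset",
    "save_dataset",
    "load_dataset",
]

VALID_DURATIONS = (1, 2, 4)
ICTAL, INTERICTAL = 1, 0


class ImbalanceError(SdcaeError, ValueError):
    """Fewer interictal candidates than ictal segments."""


class StratificationError(SdcaeError, ValueError):
    """A class has fewer members than the number of folds."""


class DegenerateDataError(SdcaeError, ValueError):
    """Zero pooled variance: normalization undefined."""


@dataclass(frozen=True)
class Segment:
    """One labeled (L x N) window; L = sample_rate * duration, N channels."""

    data: np.ndarray
    label: int
    subject_id: str
    start_s: float


@dataclass(frozen=True)
class NormalizationParams:
    """Global z-score and min–max statistics, in acquisition units (uV)."""

    mu: float
    sigma: float
    min_z: float
    max_z: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        z = (x - self.mu) / self.sigma
        return (z - self.min_z) / (self.max_z - self.min_z)


@dataclass
class SegmentDataset:
    """Stacked model-ready segments: X in [0,1], shape (n, L, width, 1)."""

    X: np.ndarray
    y: np.ndarray
    norm: NormalizationParams
    subject_ids: list[str]
    start_s: np.ndarray
    fold_of: np.ndarray | None = None

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def width(self) -> int:
        return self.X.shape[2]


def extract_segments(
    rec: Recording,
    ann: AnnotationSet,
    duration_s: int,
    buffer_s: float = 0.0,
) -> list[Segment]:
    """Tile a recording into non-overlapping labeled segments.

    Ictal windows start at each seizure onset and advance by the window
    length; a trailing partial window is dropped.  Interictal windows tile
    the recording from t=0 and are kept only if they have zero overlap with
    any seizure interval enlarged by ``buffer_s`` on both sides.  Because
    every ictal window lies inside its seizure interval, no interictal
    window ever shares samples with an ictal one.
    """
    if duration_s not in VALID_DURATIONS:
        raise ValidationError(f"duration must be one of {VALID_DURATIONS}, got {duration_s}")
    sr = rec.sample_rate_hz
    L = int(round(sr * duration_s))
    segments: list[Segment] = []

    for iv in ann.intervals:
        start = iv.start_s
        while start + duration_s <= iv.end_s + 1e-9:
            lo = int(round(start * sr))
            if lo + L <= rec.n_samples:
                segments.append(
                    Segment(rec.signal[lo: lo + L], ICTAL, rec.subject_id, round(start, 6))
                )
            start += duration_s

    buffered = [
        (iv.start_s - buffer_s, iv.end_s + buffer_s) for iv in ann.intervals
    ]
    n_windows = rec.n_samples // L
    for w in range(n_windows):
        t0 = w * L / sr
        t1 = t0 + duration_s
        if any(t0 < hi and lo < t1 for lo, hi in buffered):
            continue
        segments.append(
            Segment(rec.signal[w * L: (w + 1) * L], INTERICTAL, rec.subject_id, round(t0, 6))
        )
    return segments


def balance_dataset(
    ictal: list[Segment], interictal: list[Segment], seed: int
) -> list[Segment]:
    """All ictal segments plus an equal-size seeded random interictal sample."""
    if len(interictal) < len(ictal):
        raise ImbalanceError(
            f"{len(interictal)} interictal candidates < {len(ictal)} ictal segments"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(interictal), size=len(ictal), replace=False)
    return list(ictal) + [interictal[int(i)] for i in sorted(chosen)]


def normalize_dataset(
    segments: list[Segment],
) -> tuple[SegmentDataset, NormalizationParams]:
    """Global z-score then global min–max over the pooled segment stack.

    One (mu, sigma) is computed over all values of all channels and
    segments jointly; the z-scored values are then mapped onto [0, 1] by
    one global min–max.  Both parameter pairs are returned so unseen data
    can be mapped through the identical transform.
    """
    if len(segments) < 2:
        raise ValidationError("need at least 2 segments to normalize")
    X = np.stack([s.data for s in segments]).astype(np.float64)
    mu = float(X.mean())
    sigma = float(X.std())
    if sigma <= 0:
        raise DegenerateDataError("pooled standard deviation is zero")
    Z = (X - mu) / sigma
    min_z, max_z = float(Z.min()), float(Z.max())
    if not max_z > min_z:
        raise DegenerateDataError("degenerate value range after z-scoring")
    X01 = (Z - min_z) / (max_z - min_z)

    params = NormalizationParams(mu=mu, sigma=sigma, min_z=min_z, max_z=max_z)
    ds = SegmentDataset(
        X=X01[..., None],
        y=np.array([s.label for s in segments], dtype=np.int64),
        norm=params,
        subject_ids=[s.subject_id for s in segments],
        start_s=np.array([s.start_s for s in segments]),
    )
    return ds, params


def pad_channel_dim(ds: SegmentDataset, policy: str = "zeros") -> SegmentDataset:
    """Extend the channel dimension 23 -> 24 so three width-halvings and one
    width-thirding reduce it exactly to 1 inside the encoder.

    ``policy`` is ``"zeros"`` (inert extra column) or ``"replicate-last"``.
    """
    if ds.width != 23:
        raise ValidationError(f"expected width 23 before padding, got {ds.width}")
    if policy == "zeros":
        pad = np.zeros_like(ds.X[:, :, :1, :])
    elif policy == "replicate-last":
        pad = ds.X[:, :, -1:, :].copy()
    else:
        raise ValidationError(f"unknown padding policy {policy!r}")
    return replace(ds, X=np.concatenate([ds.X, pad], axis=2))


def assign_stratified_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold index per segment: per-class fold sizes differ by <= 1."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise StratificationError("both classes must be present for stratification")
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_of[test_idx] = fold
    return fold_of


def build_dataset(
    cohort: list[tuple[Recording, list[SeizureInterval]]],
    duration_s: int,
    seed: int = 0,
    buffer_s: float = 0.0,
    min_seizure_s: float = 10.0,
    k: int = 10,
    pad_policy: str = "zeros",
) -> SegmentDataset:
    """Full builder: tile, filter short seizures, balance, normalize, pad, fold."""
    from .eeg_io import filter_seizures

    ictal: list[Segment] = []
    interictal: list[Segment] = []
    for rec, intervals in cohort:
        ann = AnnotationSet(subject_id=rec.subject_id, intervals=list(intervals))
        ann = filter_seizures(ann, min_seizure_s)
        for seg in extract_segments(rec, ann, duration_s, buffer_s):
            (ictal if seg.label == ICTAL else interictal).append(seg)
    balanced = balance_dataset(ictal, interictal, seed)
    ds, _ = normalize_dataset(balanced)
    ds = pad_channel_dim(ds, pad_policy)
    ds.fold_of = assign_stratified_folds(ds.y, k=k, seed=seed)
    return ds


def save_dataset(ds: SegmentDataset, path) -> None:
    """Persist a dataset as a single .npz archive."""
    np.savez_compressed(
        path,
        X=ds.X,
        y=ds.y,
        fold_of=ds.fold_of if ds.fold_of is not None else np.array([]),
        start_s=ds.start_s,
        subject_ids=np.array(ds.subject_ids),
        norm=np.array([ds.norm.mu, ds.norm.sigma, ds.norm.min_z, ds.norm.max_z]),
    )


def load_dataset(path) -> SegmentDataset:
    with np.load(path, allow_pickle=False) as z:
        norm = NormalizationParams(*map(float, z["norm"]))
        fold_of = z["fold_of"] if z["fold_of"].size else None
        return SegmentDataset(
            X=z["X"],
            y=z["y"],
            norm=norm,
            subject_ids=[str(s) for s in z["subject_ids"]],
            start_s=z["start_s"],
            fold_of=fold_of,
        )
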