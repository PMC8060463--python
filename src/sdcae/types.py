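"""Core domain types shared across the pipeline.

A :class:`Recording` is one subject's multichannel scalp EEG held as a
(samples x channels) float array in microvolts, together with its sample
rate and channel labels.  Seizure annotations are kept separately as
:class:`SeizureInterval` lists inside an :class:`AnnotationSet`, mirroring
how the CHB-MIT corpus ships signal files (EDF) and annotations
(plain-text summary files) side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SdcaeError",
    "ValidationError",
    "EdfParseError",
    "SummaryParseError",
    "FormatError",
    "ChannelError",
    "SeizureInterval",
    "Recording",
    "AnnotationSet",
]


class SdcaeError(Exception):
    """Base class for all package errors."""


class ValidationError(SdcaeError, ValueError):
    """Invalid domain value (bad interval, bad spec field, ...)."""


class EdfParseError(SdcaeError, ValueError):
    """Malformed or truncated EDF file."""


class SummaryParseError(SdcaeError, ValueError):
    """Malformed seizure-summary text (count/pair mismatch etc.)."""


class FormatError(SdcaeError, ValueError):
    """Well-formed file that violates a pipeline contract (e.g. sample rate)."""


class ChannelError(SdcaeError, ValueError):
    """A required channel is missing from a recording."""


@dataclass(frozen=True, order=True)
class SeizureInterval:
    """Closed-open seizure interval ``[start_s, end_s)`` in recording time."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"seizure interval must have end > start, got ({self.start_s}, {self.end_s})"
            )
        if self.start_s < 0:
            raise ValidationError(f"seizure start must be >= 0, got {self.start_s}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def check_disjoint(intervals: list[SeizureInterval]) -> list[SeizureInterval]:
    """Sort intervals by start and verify they do not overlap."""
    out = sorted(intervals)
    for a, b in zip(out, out[1:]):
        if b.start_s < a.end_s:
            raise ValidationError(f"overlapping seizure intervals: {a} and {b}")
    return out


@dataclass
class Recording:
    """One subject's multichannel EEG signal.

    ``signal`` is (n_samples, n_channels) float64 in microvolts.
    """

    subject_id: str
    signal: np.ndarray
    sample_rate_hz: float
    channel_names: list[str]
    source_file: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (samples x channels)")
        if self.signal.shape[1] != len(self.channel_names):
            raise ValidationError(
                f"{self.signal.shape[1]} signal columns but "
                f"{len(self.channel_names)} channel names"
            )
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class AnnotationSet:
    """Seizure intervals for one recording, sorted and non-overlapping."""

    subject_id: str
    intervals: list[SeizureInterval] = field(default_factory=list)
    source_file: str = ""

    def __post_init__(self) -> None:
        self.intervals = check_disjoint(list(self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)

    def total_duration_s(self) -> float:
        return float(sum(iv.duration_s for iv in self.intervals))
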