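"""Synthetic multichannel EEG with annotated seizure intervals.

The generator emulates the gross statistics of pediatric scalp EEG as the
pipeline consumes it: 23 channels sampled at 256 Hz, pink (1/f-shaped)
background noise around 20 uV, and seizure periods carrying a rhythmic
~3 Hz spike-and-wave discharge of much larger amplitude on most channels.
It makes every downstream stage (EDF I/O, segmentation, model training,
cross-validation) testable without downloading any clinical data.  It is
not a physiological simulator: no artifacts, no montage structure, no
state transitions beyond ictal/background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import Recording, SeizureInterval, ValidationError, check_disjoint

__all__ = ["SignalSpec", "generate_recording", "make_toy_cohort"]


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of one synthetic recording.

    Amplitudes are standard deviations in microvolts; ``channel_involvement``
    is the fraction of channels that carry the ictal discharge (generalized
    seizures involve most of the scalp, so the default is 1.0).
    """

    duration_s: float
    n_channels: int = 23
    sample_rate_hz: float = 256.0
    background_amp_uv: float = 20.0
    ictal_amp_uv: float = 100.0
    ictal_freq_hz: float = 3.0
    channel_involvement: float = 1.0
    n_sources: int = 8
    sensor_noise_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be > 0")
        if self.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")
        if not (0 < self.channel_involvement <= 1):
            raise ValidationError("channel_involvement must be in (0, 1]")
        if self.n_sources < 1:
            raise ValidationError("n_sources must be >= 1")
        if not (0 <= self.sensor_noise_frac <= 1):
            raise ValidationError("sensor_noise_frac must be in [0, 1]")
        if self.ictal_amp_uv <= self.background_amp_uv:
            raise ValidationError(
                "ictal_amp_uv must exceed background_amp_uv for separable classes"
            )


def _pink_noise(rng: np.random.Generator, n_samples: int, n_channels: int) -> np.ndarray:
    """Gaussian noise spectrally shaped to ~1/f power, unit variance per channel."""
    white = rng.standard_normal((n_samples, n_channels))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n_samples)
    # amplitude ~ 1/sqrt(f) => power ~ 1/f; flatten below one cycle to avoid DC blowup
    shaping = np.empty_like(freqs)
    shaping[0] = 0.0
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * shaping[:, None], n=n_samples, axis=0)
    pink /= pink.std(axis=0, keepdims=True)
    return pink


def _background(rng: np.random.Generator, n_samples: int, spec: SignalSpec) -> np.ndarray:
    """Volume-conducted background: shared pink-noise sources mixed into all
    channels, plus independent per-channel pink sensor/local noise.

    Scalp electrodes see overlapping mixtures of a modest number of cortical
    generators, which is what makes real EEG strongly inter-channel
    correlated; ``sensor_noise_frac`` of the background power stays
    channel-independent.  Each channel is scaled to ``background_amp_uv``.
    """
    sources = _pink_noise(rng, n_samples, spec.n_sources)
    mixing = rng.standard_normal((spec.n_sources, spec.n_channels))
    mixing /= np.linalg.norm(mixing, axis=0, keepdims=True)
    shared = sources @ mixing
    shared /= shared.std(axis=0, keepdims=True)
    local = _pink_noise(rng, n_samples, spec.n_channels)
    bg = np.sqrt(1.0 - spec.sensor_noise_frac) * shared + np.sqrt(spec.sensor_noise_frac) * local
    return spec.background_amp_uv * bg / bg.std(axis=0, keepdims=True)


def _spike_wave(t: np.ndarray, freq_hz: float, phase: float) -> np.ndarray:
    """Fundamental plus decaying harmonics: a crude spike-and-wave complex."""
    w = 2 * math.pi * freq_hz
    s = (
        np.sin(w * t + phase)
        + 0.5 * np.sin(2 * w * t + 2 * phase)
        + 0.25 * np.sin(3 * w * t + 3 * phase)
    )
    return s / np.abs(s).max()


def generate_recording(
    spec: SignalSpec, seizures: list[SeizureInterval] | None = None, subject_id: str = "synth"
) -> tuple[Recording, list[SeizureInterval]]:
    """Generate one recording; returns ``(Recording, sorted seizure list)``.

    Samples inside the given intervals carry the rhythmic ictal component at
    ``ictal_freq_hz`` with amplitude ``ictal_amp_uv`` on
    ``ceil(channel_involvement * n_channels)`` channels, superimposed on the
    1/f background present everywhere.  Identical inputs give bit-identical
    output.
    """
    seizures = check_disjoint(list(seizures or []))
    for iv in seizures:
        if iv.end_s > spec.duration_s:
            raise ValidationError(
                f"seizure interval {iv} extends past recording end ({spec.duration_s} s)"
            )

    n_samples = int(round(spec.duration_s * spec.sample_rate_hz))
    rng = np.random.default_rng(spec.seed)
    signal = _background(rng, n_samples, spec)

    n_involved = math.ceil(spec.channel_involvement * spec.n_channels)
    t = np.arange(n_samples) / spec.sample_rate_hz
    for iv in seizures:
        lo = int(round(iv.start_s * spec.sample_rate_hz))
        hi = int(round(iv.end_s * spec.sample_rate_hz))
        channels = rng.permutation(spec.n_channels)[:n_involved]
        # generalized spike-and-wave is bilaterally synchronous: one discharge
        # phase per seizure, with small per-channel lag and amplitude spread
        phase0 = rng.uniform(0, 2 * math.pi)
        jitter = rng.uniform(-0.3, 0.3, size=n_involved)
        amp = spec.ictal_amp_uv * rng.uniform(0.8, 1.2, size=n_involved)
        for ch, dphi, a in zip(channels, jitter, amp):
            signal[lo:hi, ch] += a * _spike_wave(t[lo:hi], spec.ictal_freq_hz, phase0 + dphi)

    channel_names = [f"SYN{j:02d}" for j in range(spec.n_channels)]
    rec = Recording(
        subject_id=subject_id,
        signal=signal,
        sample_rate_hz=spec.sample_rate_hz,
        channel_names=channel_names,
        source_file="<synthetic>",
    )
    return rec, seizures


def make_toy_cohort(
    n_subjects: int,
    seizures_per_subject: int,
    seed: int = 0,
    spec: SignalSpec | None = None,
    min_seizure_s: float = 12.0,
    max_seizure_s: float = 40.0,
    gap_s: float = 60.0,
) -> list[tuple[Recording, list[SeizureInterval]]]:
    """Deterministic cohort of synthetic subjects.

    Each subject gets its own derived seed (``seed + index``) so subjects
    differ but the cohort is reproducible.  Every seizure is at least
    ``min_seizure_s`` long (>= the 10 s duration filter downstream), and
    seizures are separated by at least ``gap_s`` of background so plenty of
    interictal data exists for class balancing.
    """
    if n_subjects < 1 or seizures_per_subject < 1:
        raise ValidationError("n_subjects and seizures_per_subject must be >= 1")
    if min_seizure_s < 10.0:
        raise ValidationError("min_seizure_s below the 10 s inclusion rule")

    cohort: list[tuple[Recording, list[SeizureInterval]]] = []
    for idx in range(n_subjects):
        subject_seed = seed + idx
        rng = np.random.default_rng(subject_seed)
        durations = rng.uniform(min_seizure_s, max_seizure_s, size=seizures_per_subject)
        total = float(gap_s + np.sum(durations + gap_s))
        from dataclasses import replace as _replace

        base = spec or SignalSpec(duration_s=total, seed=subject_seed)
        sub_spec = _replace(base, duration_s=total, seed=subject_seed)
        start = gap_s
        intervals = []
        for d in durations:
            intervals.append(SeizureInterval(round(start, 3), round(start + float(d), 3)))
            start += float(d) + gap_s
        rec, ann = generate_recording(sub_spec, intervals, subject_id=f"syn{idx:02d}")
        cohort.append((rec, ann))
    return cohort
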