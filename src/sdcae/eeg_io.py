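"""EDF recordings and CHB-MIT-style seizure annotations.

Reading EDF goes through MNE; writing uses a small built-in EDF writer
(16-bit, one-second data records) so synthetic cohorts can round-trip
through the same on-disk formats as the clinical corpus.  Seizure
annotations are parsed from the plain-text summary dialect used by the
CHB-MIT Scalp EEG Database (``chbXX-summary.txt``): blocks of
``File Name`` / ``Number of Seizures in File`` lines followed by one
``Seizure Start Time`` / ``Seizure End Time`` pair per seizure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import (
    AnnotationSet,
    ChannelError,
    EdfParseError,
    FormatError,
    Recording,
    SeizureInterval,
    SummaryParseError,
    ValidationError,
)

__all__ = [
    "CHBMIT_CHANNELS",
    "read_edf",
    "write_edf",
    "parse_summary",
    "write_summary",
    "SummarySet",
    "canonicalize_channels",
    "filter_seizures",
    "chbmit_seizure_table",
]

# The 23-channel bipolar montage used throughout the CHB-MIT corpus
# (10-20 electrode names, modified combinatorial nomenclature).  The corpus
# genuinely repeats T8-P8; canonicalization resolves repeats to the first
# matching source column.
CHBMIT_CHANNELS: list[str] = [
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ", "P7-T7", "T7-FT9",
    "FT9-FT10", "FT10-T8", "T8-P8",
]


# ---------------------------------------------------------------------------
# EDF writing (minimal, 16-bit, 1 s records)
# ---------------------------------------------------------------------------

def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def _num(value: float, width: int) -> bytes:
    for fmt in (f"{{:.{p}g}}" for p in range(7, 0, -1)):
        s = fmt.format(value)
        if len(s) <= width:
            return _ascii(s, width)
    raise ValidationError(f"cannot format {value!r} in {width} EDF header chars")


def write_edf(path: str | Path, rec: Recording) -> Path:
    """Write a recording as plain EDF with 16-bit samples.

    The sample rate must be a whole number of samples per one-second data
    record; a trailing partial second is dropped.  Physical units are
    microvolts with a symmetric physical range, so the quantization step is
    ``2 * max|signal| / 65535`` uV.
    """
    path = Path(path)
    sr = rec.sample_rate_hz
    if abs(sr - round(sr)) > 1e-9:
        raise FormatError(f"EDF writer needs an integer sample rate, got {sr}")
    spr = int(round(sr))
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValidationError("recording shorter than one EDF data record (1 s)")
    nch = rec.n_channels

    pmax = float(np.max(np.abs(rec.signal))) or 1.0
    dig_max, dig_min = 32767, -32768
    scale = dig_max / pmax

    header = b"".join([
        _ascii("0", 8),
        _ascii(rec.subject_id, 80),
        _ascii("sdcae synthetic EEG", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(str(256 * (nch + 1)), 8),
        _ascii("", 44),
        _ascii(str(n_records), 8),
        _ascii("1", 8),
        _ascii(str(nch), 4),
    ])
    labels = [_ascii(name, 16) for name in rec.channel_names]
    header += b"".join(labels)
    header += b"".join(_ascii("", 80) for _ in range(nch))            # transducer
    header += b"".join(_ascii("uV", 8) for _ in range(nch))           # physical dim
    header += b"".join(_num(-pmax, 8) for _ in range(nch))            # physical min
    header += b"".join(_num(pmax, 8) for _ in range(nch))             # physical max
    header += b"".join(_num(dig_min, 8) for _ in range(nch))          # digital min
    header += b"".join(_num(dig_max, 8) for _ in range(nch))          # digital max
    header += b"".join(_ascii("", 80) for _ in range(nch))            # prefiltering
    header += b"".join(_ascii(str(spr), 8) for _ in range(nch))       # samples/record
    header += b"".join(_ascii("", 32) for _ in range(nch))            # reserved

    digital = np.clip(np.round(rec.signal[: n_records * spr] * scale), dig_min, dig_max)
    digital = digital.astype("<i2")
    # EDF interleaves per record: all samples of ch0, then ch1, ...
    records = digital.reshape(n_records, spr, nch).transpose(0, 2, 1)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(records.tobytes())
    return path


# ---------------------------------------------------------------------------
# EDF reading (MNE-backed, with a light header pre-check)
# ---------------------------------------------------------------------------

def _precheck_edf(path: Path) -> None:
    """Validate structural header fields before handing the file to MNE."""
    try:
        with open(path, "rb") as fh:
            head = fh.read(256)
            if len(head) < 256:
                raise EdfParseError(f"{path}: truncated EDF header")
            n_records = int(head[236:244].decode("ascii", "replace").strip() or -1)
            nch = int(head[252:256].decode("ascii", "replace").strip())
            sig_head = fh.read(256 * nch)
            if len(sig_head) < 256 * nch or nch <= 0:
                raise EdfParseError(f"{path}: truncated EDF signal headers")
            off = 216 * nch  # samples-per-record block offset within signal headers
            spr = [
                int(sig_head[off + 8 * j: off + 8 * (j + 1)].decode("ascii", "replace").strip())
                for j in range(nch)
            ]
            data = fh.seek(0, 2) - 256 * (nch + 1)
    except (ValueError, OSError) as exc:
        raise EdfParseError(f"{path}: malformed EDF header ({exc})") from exc
    eeg_spr = {s for s in spr}
    if len(eeg_spr) > 1:
        raise FormatError(f"{path}: channels disagree on samples per record: {sorted(eeg_spr)}")
    if n_records >= 0 and data < n_records * sum(spr) * 2:
        raise EdfParseError(f"{path}: file shorter than declared data records")


def read_edf(path: str | Path, expected_rate_hz: float | None = 256.0) -> Recording:
    """Read an EDF file into a :class:`Recording` (microvolts, float64).

    Channel labels are preserved verbatim.  If ``expected_rate_hz`` is given,
    a differing sample rate raises :class:`FormatError` — the pipeline
    requires one common rate across a dataset.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise EdfParseError(f"{path}: no such file")
    _precheck_edf(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed input
        raise EdfParseError(f"{path}: MNE failed to parse EDF ({exc})") from exc

    sr = float(raw.info["sfreq"])
    if expected_rate_hz is not None and abs(sr - expected_rate_hz) > 1e-6:
        raise FormatError(f"{path}: sample rate {sr} Hz, pipeline expects {expected_rate_hz} Hz")
    data_v = raw.get_data()  # (channels, samples) in volts
    return Recording(
        subject_id=path.stem,
        signal=np.ascontiguousarray(data_v.T) * 1e6,
        sample_rate_hz=sr,
        channel_names=[str(c) for c in raw.ch_names],
        source_file=str(path),
    )


# ---------------------------------------------------------------------------
# Summary annotations
# ---------------------------------------------------------------------------

@dataclass
class SummarySet:
    """All annotations from one subject summary file, keyed by EDF file name."""

    subject_id: str
    by_file: dict[str, AnnotationSet] = field(default_factory=dict)

    def all_intervals(self) -> list[SeizureInterval]:
        return [iv for ann in self.by_file.values() for iv in ann.intervals]

    @property
    def n_seizures(self) -> int:
        return len(self.all_intervals())

    @property
    def total_duration_s(self) -> float:
        return float(sum(iv.duration_s for iv in self.all_intervals()))


_FILE_RE = re.compile(r"^File Name:\s*(\S+)", re.M)
_COUNT_RE = re.compile(r"^Number of Seizures in File:\s*(\d+)", re.M)
_START_RE = re.compile(r"^Seizure(?:\s+\d+)? Start Time:\s*([\d.]+)\s*sec", re.M)
_END_RE = re.compile(r"^Seizure(?:\s+\d+)? End Time:\s*([\d.]+)\s*sec", re.M)


def parse_summary(path: str | Path) -> SummarySet:
    """Parse a CHB-MIT-dialect summary text file.

    Each ``File Name`` block must declare its seizure count and contain
    exactly that many start/end pairs; a mismatch raises
    :class:`SummaryParseError`, and ``end <= start`` raises
    :class:`ValidationError`.
    """
    path = Path(path)
    text = path.read_text()
    subject_id = path.stem.replace("-summary", "")

    blocks = _FILE_RE.split(text)
    # blocks: [preamble, fname1, body1, fname2, body2, ...]
    out = SummarySet(subject_id=subject_id)
    for fname, body in zip(blocks[1::2], blocks[2::2]):
        m = _COUNT_RE.search(body)
        if m is None:
            raise SummaryParseError(f"{path}: block {fname} lacks a seizure count line")
        declared = int(m.group(1))
        starts = [float(s) for s in _START_RE.findall(body)]
        ends = [float(s) for s in _END_RE.findall(body)]
        if len(starts) != declared or len(ends) != declared:
            raise SummaryParseError(
                f"{path}: block {fname} declares {declared} seizures but lists "
                f"{len(starts)} start / {len(ends)} end times"
            )
        intervals = [SeizureInterval(s, e) for s, e in zip(starts, ends)]
        out.by_file[fname] = AnnotationSet(
            subject_id=subject_id, intervals=intervals, source_file=fname
        )
    return out


def write_summary(path: str | Path, subject_id: str, files: dict[str, list[SeizureInterval]],
                  sample_rate_hz: float = 256.0) -> Path:
    """Write annotations in the CHB-MIT summary dialect (inverse of parse)."""
    lines = [f"Data Sampling Rate: {sample_rate_hz:g} Hz", "*" * 25, ""]
    for fname, intervals in files.items():
        lines.append(f"File Name: {fname}")
        lines.append(f"Number of Seizures in File: {len(intervals)}")
        for iv in intervals:
            lines.append(f"Seizure Start Time: {iv.start_s:g} seconds")
            lines.append(f"Seizure End Time: {iv.end_s:g} seconds")
        lines.append("")
    path = Path(path)
    path.write_text("\n".join(lines))
    return path


# ---------------------------------------------------------------------------
# Channel canonicalization and seizure filtering
# ---------------------------------------------------------------------------

def _norm_label(label: str) -> str:
    return label.strip().upper()


def canonicalize_channels(rec: Recording, canonical: list[str] | None = None) -> Recording:
    """Reorder columns to a fixed canonical montage.

    Matching is case-insensitive and whitespace-tolerant; extra channels are
    dropped; a label occurring more than once in the source resolves to its
    first occurrence.  A canonical label absent from the recording raises
    :class:`ChannelError` naming it.
    """
    canonical = list(canonical or CHBMIT_CHANNELS)
    first_index: dict[str, int] = {}
    for j, name in enumerate(rec.channel_names):
        first_index.setdefault(_norm_label(name), j)
    cols = []
    for name in canonical:
        j = first_index.get(_norm_label(name))
        if j is None:
            raise ChannelError(f"recording {rec.subject_id!r} lacks canonical channel {name!r}")
        cols.append(j)
    return Recording(
        subject_id=rec.subject_id,
        signal=rec.signal[:, cols],
        sample_rate_hz=rec.sample_rate_hz,
        channel_names=list(canonical),
        source_file=rec.source_file,
    )


def filter_seizures(ann: AnnotationSet, min_duration_s: float = 10.0) -> AnnotationSet:
    """Drop seizures shorter than ``min_duration_s`` (default: the 10 s rule)."""
    kept = [iv for iv in ann.intervals if iv.duration_s >= min_duration_s]
    return AnnotationSet(subject_id=ann.subject_id, intervals=kept, source_file=ann.source_file)


def chbmit_seizure_table(root: str | Path, subjects: list[str]):
    """Aggregate per-subject seizure counts and total durations.

    Expects ``root/<subject>/<subject>-summary.txt`` as the CHB-MIT corpus is
    laid out; returns a DataFrame with one row per subject plus a Total row.
    Useful for verifying a local copy of the corpus against published counts.
    """
    import pandas as pd

    rows = []
    for sub in subjects:
        summ = parse_summary(Path(root) / sub / f"{sub}-summary.txt")
        rows.append({
            "subject": sub,
            "n_seizures": summ.n_seizures,
            "total_duration_s": summ.total_duration_s,
        })
    df = pd.DataFrame(rows)
    total = {"subject": "Total",
             "n_seizures": int(df["n_seizures"].sum()),
             "total_duration_s": float(df["total_duration_s"].sum())}
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
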