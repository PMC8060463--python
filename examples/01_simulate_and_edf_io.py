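"""Generate a synthetic EEG recording and round-trip it through EDF.

Writes a 23-channel, 256 Hz recording with one annotated seizure to EDF
plus a CHB-MIT-dialect summary file, reads both back, and reports the
quantization error of the 16-bit round trip.
"""

import tempfile
from pathlib import Path

import numpy as np

from sdcae import (
    SignalSpec,
    generate_recording,
    parse_summary,
    read_edf,
    write_edf,
    write_summary,
)
from sdcae.types import SeizureInterval

spec = SignalSpec(duration_s=120.0, seed=42)
rec, seizures = generate_recording(spec, [SeizureInterval(30.0, 55.0)], subject_id="demo")
print(f"generated: {rec.signal.shape[0]} samples x {rec.n_channels} channels "
      f"({rec.duration_s:.0f} s at {rec.sample_rate_hz:.0f} Hz)")

with tempfile.TemporaryDirectory() as tmp:
    edf = write_edf(Path(tmp) / "demo.edf", rec)
    summary = write_summary(Path(tmp) / "demo-summary.txt", "demo",
                            {"demo.edf": seizures})
    back = read_edf(edf)
    ann = parse_summary(summary)

err = np.abs(back.signal - rec.signal).max()
step = 2 * np.abs(rec.signal).max() / 65535
print(f"EDF round-trip max error: {err:.4f} uV (16-bit quantization step {step:.4f} uV)")
iv = ann.by_file["demo.edf"].intervals[0]
print(f"annotation round-trip: seizure [{iv.start_s:.0f}, {iv.end_s:.0f}] s, "
      f"duration {iv.duration_s:.0f} s")
print("-> signal survives to within quantization; annotations parse back exactly.")
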