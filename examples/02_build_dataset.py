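"""Build the balanced, normalized, fold-assigned segment dataset.

Creates a small synthetic cohort, tiles it into 2 s windows, balances the
classes, applies the global z-score + min-max normalization, pads the
channel axis to 24, and assigns stratified 10-fold labels.
"""

import numpy as np

from sdcae import build_dataset, make_toy_cohort

cohort = make_toy_cohort(n_subjects=4, seizures_per_subject=3, seed=11)
total_seizure = sum(iv.duration_s for _, ann in cohort for iv in ann)
print(f"cohort: {len(cohort)} subjects, "
      f"{sum(len(a) for _, a in cohort)} seizures, {total_seizure:.0f} s ictal time")

ds = build_dataset(cohort, duration_s=2, seed=11)
print(f"dataset X: {ds.X.shape}  (segments x 512 samples x 24 channels x 1)")
print(f"class balance: {int(np.sum(ds.y == 1))} ictal / {int(np.sum(ds.y == 0))} interictal")
print(f"value range after normalization: [{ds.X.min():.3f}, {ds.X.max():.3f}]")
print(f"normalization: mu={ds.norm.mu:.3f} uV, sigma={ds.norm.sigma:.3f} uV, "
      f"z-range [{ds.norm.min_z:.2f}, {ds.norm.max_z:.2f}]")
sizes = [int(np.sum(ds.fold_of == f)) for f in range(10)]
print(f"stratified fold sizes: {sizes}")
print("-> equal class counts, values in [0,1], folds within one segment of each other.")
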