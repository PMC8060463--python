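"""Stratified cross-validation over a model grid plus significance testing.

Runs a desk-scale 2-fold grid (two variants at 1 s segments) on a small
synthetic cohort, prints the metric table, and compares the fold
accuracies of the two variants with the Kruskal–Wallis H test.
"""

from sdcae import build_dataset, cross_validate, kruskal_wallis, make_toy_cohort, render_report
from sdcae.nn.models import ModelConfig
from sdcae.training import TrainingConfig

cohort = make_toy_cohort(n_subjects=2, seizures_per_subject=2, seed=4)
ds = build_dataset(cohort, duration_s=1, seed=4, k=4)

summaries = cross_validate(
    {1: ds}, ["DCAE_MLP", "DCNN_MLP"],
    TrainingConfig(epochs=8, batch_size=16, learning_rate=1e-3, seed=4),
    config_for=lambda v, d: ModelConfig(v, duration_s=d).tiny(16),
    base_seed=4,
)
df = render_report(summaries)
print(df[["variant", "accuracy_mean", "accuracy_std", "f1_mean"]].round(2).to_string(index=False))

acc = {s.variant: [m.accuracy for m in s.fold_metrics] for s in summaries}
h, p = kruskal_wallis([acc["DCAE_MLP"], acc["DCNN_MLP"]])
print(f"Kruskal-Wallis on fold accuracies: H={h:.3f}, p={p:.3f}")
print("-> mean +/- std per variant over folds; the H test asks whether the two")
print("   fold-accuracy samples come from the same distribution (p<0.05: they differ).")
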