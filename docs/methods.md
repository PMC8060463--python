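# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `sdcae`, in the spirit of a package methods section.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem and pipeline

The task is binary classification of fixed-length multichannel scalp-EEG
windows into ictal (seizure, positive) and interictal (between-seizure,
negative) states, for pediatric recordings sampled at 256 Hz on a
23-channel bipolar montage.  The pipeline is:

1. **Annotation filtering.** Seizures shorter than 10 s are discarded
   (`min_duration_s`, default 10): very short events are unreliable as
   training labels.
2. **Segmentation.** Non-overlapping windows of 1, 2 or 4 s.  Ictal
   windows tile each seizure interval from its onset; the trailing
   partial window is dropped (simplest rule that preserves
   non-overlap).  Interictal candidates tile the recording from t = 0 and
   must have zero overlap with any seizure interval, optionally enlarged
   by an exclusion buffer (default 0 s; a hygiene option, not the
   reference behaviour).  Because ictal windows lie inside their seizure,
   interictal and ictal windows can never share samples.
3. **Balancing.** All ictal segments plus a uniformly random, seeded,
   without-replacement sample of interictal candidates of equal size,
   pooled across subjects.
4. **Normalization.** One global z-score (single μ, σ over every value of
   every channel and segment), then one global min–max onto [0, 1].
   Both statistics are deliberately computed over the *whole* assembled
   dataset before fold splitting, reproducing the reference protocol
   exactly; this leaks test-set statistics into training and is flagged
   as such.  A leakage-free alternative (fit `NormalizationParams` on
   training folds, apply elsewhere) is available through the same API.
5. **Channel padding.** 23 → 24 columns (zeros by default; inert under
   convolution and reversible.  `replicate-last` is available).  24 is
   needed so the encoder's width reductions 24 → 12 → 6 → 3 → 1 are exact.
6. **Folds.** Stratified 10-fold assignment at segment level over the
   pooled cross-patient dataset (per-class fold sizes differ by ≤ 1).
   Patient-level splitting is out of scope by design.

## Architectures

All four variants share the encoder: four blocks of
(3 × 2)-kernel, stride-1, same-padded convolution (ReLU) → batch
normalization → max pooling ((2, 2), (2, 2), (2, 2), (2, 3)), with
32/32/64/64 filters.  A (256·d, 24, 1) input becomes a (16·d, 1, 64)
latent map.  Design choices the reference description leaves open:

* **Kernel orientation** is 3 along time × 2 along channels — the only
  orientation consistent with a (2, 3) pool reducing width 3 → 1 after
  three (2, 2) pools from 24.
* **Decoder block order** is upsample → convolution, mirroring the
  encoder; filters 64/32/32/1, upsampling (2, 3) then three (2, 2),
  nearest-neighbour (the cheapest contract to test, and the default of
  the framework the original models were built in).  The final
  convolution ends in a sigmoid, so reconstructions live in [0, 1] like
  the normalized inputs.  No batch norm in the decoder (exactly four
  batch-norm layers, all in the encoder).
* **MLP head**: flatten → 50 → 32 → 1 (ReLU, ReLU, sigmoid).
* **Bi-LSTM head**: the latent (16·d, 1, 64) is read as a (16·d)-step
  sequence of 64 features; one 50-unit LSTM per direction ("50 units" is
  interpreted as 50 per direction); per-step forward/backward outputs are
  concatenated (100 features) and averaged over time; dropout 0.1
  (training only) on that average; a single sigmoid output unit with no
  hidden layer in between.
* **LSTM cell**: standard gates over the concatenated [h_{t−1}, x_t]
  vector — f, i, o sigmoid gates, tanh candidate, c_t = f⊙c_{t−1} + i⊙c̃,
  h_t = o⊙tanh(c_t) — with a unit forget-gate bias at initialization.
* **Initialization** is Glorot-uniform from a seeded generator; models
  are bit-reproducible given (config, seed).

DCNN variants drop every decoder layer and keep everything else.

## Training

The supervised autoencoder minimizes TL = w_c·CL + w_r·RL in one run
(w_c = 0.5, w_r = 1): CL is binary cross-entropy over the batch
(predictions clipped to [1e−7, 1 − 1e−7]); RL is the mean over segments
of the per-segment mean squared reconstruction error.  The batch is the N
in both losses.  DCNN variants train on CL alone.  Optimization is Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e−7) with learning rate 1e−4 at full scale,
batch 32, seeded reshuffling each epoch, fixed epoch count (200 at full
scale), no early stopping or schedule.

All forward/backward math is NumPy float64.  Gradients are exact: the
test suite checks backpropagation through the full joint loss against
central finite differences on a ≤ 500-parameter model at 1e−4 relative
tolerance (parameters are first nudged off exact ReLU kinks, where the
objective is genuinely non-differentiable and a two-sided difference
measures the subgradient midpoint instead).

**Batch normalization** uses ε = 1e−3 and a running-statistics decay of
0.9 per update.  The decay matters at desk scale: with only a few hundred
optimizer steps, a 0.99 decay leaves the inference-time running estimates
dominated by their (0, 1) initialization while training always uses batch
statistics, so train and inference behaviour diverge grossly.  0.9 makes
the estimates converge within ~50 steps and is a common framework
default.

**Max-pool gradients** share the gradient equally among exactly-tied
maxima (a valid subgradient; ties have measure zero for continuous
inputs).

## Synthetic EEG

The generator emulates only what the pipeline consumes:

* **Background** follows the standard EEG forward model: 8 shared
  pink-noise (1/f-power) sources mixed into all channels through a random
  seeded mixing matrix (volume conduction makes real scalp channels
  strongly correlated), plus 30% channel-independent pink sensor noise;
  each channel is scaled to 20 µV standard deviation.
* **Seizures** add a rhythmic 3 Hz discharge — fundamental plus decaying
  harmonics at 2f and 3f, a crude spike-and-wave complex — of 100 µV
  nominal amplitude on ⌈involvement × 23⌉ channels (default: all).  The
  discharge is bilaterally synchronous, as generalized 3 Hz spike-and-wave
  is: one phase per seizure with ±0.3 rad per-channel jitter and
  0.8–1.2× per-channel amplitude spread.  (Channel-independent random
  phases were rejected: they are physiologically wrong and make the ictal
  class nearly incompressible for a width-collapsing convolutional
  decoder, so reconstruction quality would measure a generator artifact.)
* **Cohorts** derive per-subject seeds as `seed + index`; every seizure
  is ≥ 12 s (clearing the 10 s filter), separated by ≥ 60 s of
  background.

What it does **not** model: artifacts (blinks, EMG, electrode pops),
montage geometry, inter-subject spectral variability, seizure evolution
(onset/offset dynamics, focal spread), or realistic ictal morphology
beyond a harmonic stack.  Consequently, passing desk-scale tests shows
the implementation can learn and reconstruct separable rhythmic
structure — it says nothing about clinical-scale performance on real
recordings, where class overlap, artifacts and patient variability
dominate.

## Evaluation and statistics

Held-out predictions are thresholded at 0.5 (ties predict ictal — the
positive class) and tallied into confusion counts with ictal positive.
Accuracy, sensitivity, specificity, precision and F1 are reported in
percent; a zero denominator yields NaN with a warning, never a silent
zero.  Fold aggregation reports mean ± sample standard deviation (n − 1)
over the k folds; each fold's model is retrained from a fresh
fold-derived seed.  Metrics are segment-wise, not event-wise (no
detection latency or false-alarm-rate analysis).

The Kruskal–Wallis H test (tie-corrected, χ² approximation with
groups − 1 degrees of freedom) compares fold-metric samples across
models; groups that are entirely identical return H = 0, p = 1 by
convention.  The χ² p-value is an approximation: against an exact
permutation null with two groups of five it is accurate to < 0.01 in the
p ≤ 0.05 tail but conservative by up to ~0.10 in the mid-range, which is
the tolerance structure the statistical tests assert.  The reference
analysis compares one autoencoder model's fold metrics against the two
decoder-free baselines per test; the implementation accepts arbitrary
group lists, so either pooling of "the two models" can be reproduced.

## Desk-scale study sizes

Full-scale training (12 models × 10 folds × 200 epochs, 32–64 filters)
is a cluster job.  The package's own benchmark surface
(`sdcae.benchmarks`) instead trains a filters÷8 DCAE + Bi-LSTM (and the
matched DCNN baseline) for 30 epochs at learning rate 1e−3 on a
400-segment balanced 2 s synthetic dataset (4 subjects × 4 seizures),
with one stratified fold held out.  1e−3 is the package's standard
learning rate for desk-scale models: the full-scale 1e−4 is matched to
200-epoch runs an order of magnitude larger.  The end-to-end CLI smoke
configuration is smaller still (2 subjects, filter divisor 16, 1–2
epochs, 2 folds) so the whole pipeline finishes in well under ten
minutes on one CPU.

## Known limitations

* The EDF writer covers plain 16-bit EDF with one-second records and
  whole-second durations — enough for round-tripping synthetic cohorts,
  not a general EDF+ implementation.
* Normalization-leakage reproduction (above) is the default; switch to
  per-split fitting for honest generalization estimates.
* Optimizers other than Adam (SGD, RMSProp, ADADELTA appear in the
  reference comparison) are not implemented; Adam was the selected one.
* Overlapping/strided windows, a preictal class, artifact rejection,
  resampling, montage re-referencing and per-patient models are all out
  of scope.
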