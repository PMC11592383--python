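# Methods

## The problem

Before epilepsy surgery the seizure onset zone (SOZ) — the cortical area
where seizures begin — must be localized. Scalp EEG (sEEG) on the
international 10–20 montage is the cheap, non-invasive signal available for
this, but reading hours of 21-channel recordings by eye is slow. The
approach implemented here reduces SOZ localization to a sequence of
single-channel decisions: a classifier that labels one second of one
channel as seizure or non-seizure is applied independently to every channel
and every second of a multi-channel recording, producing a 21 × seconds
grid of verdicts. The spatial pattern of that grid over time — where flags
appear first, how they spread, where they persist — identifies the
hemisphere of onset and the seizure type.

## Pipeline

1. **Preprocessing** (`preprocess`). Recordings are band-pass filtered to
   0.53–40 Hz, reduced to the 21 canonical 10–20 channels
   (Fp1 … Pz; T1/T2, ECG, EMG and other auxiliaries are dropped), cut into
   non-overlapping 1-s windows, resampled to 178 samples per window, and
   z-scored. Labels 2–5 of the 5-class single-channel corpus collapse to
   "non-seizure"; label 1 is "seizure".
2. **Classifier** (`cnn`). A 1-D CNN: three convolutional layers of
   20 kernels of length 5 (stride 1, valid, ReLU), each followed by
   dropout 0.5; max-pooling of width 2; flatten; a 50-unit ReLU dense
   layer; a single sigmoid output. The shape chain is
   178 → 174 → 170 → 166 → 83×20 → 1660 → 50 → 1. Probability ≥ 0.5 is a
   seizure verdict; the tie at exactly 0.5 resolves to seizure, favouring
   sensitivity.
3. **Training** (`training`). Stratified 80/20 train+validation/test
   split; 10-fold cross-validation on the 80 %; SMOTE rebalancing of the
   1:4 class imbalance; binary cross-entropy minimized by Adam
   (lr 0.001, batch 256, ≤ 200 epochs, early stopping patience 16);
   the fold with the highest validation sensitivity supplies the weights
   evaluated on the held-out test set.
4. **Detection** (`detection`). The trained single-channel model is applied
   to every channel of a recording ("21 identical models" is implemented as
   one weight set applied 21 times — identical training on identical data
   makes per-channel replicas a presentation device, not a computation).
5. **Localization** (`localization`). The first flagged second defines the
   onset; sites flagged within the following 5 s form the onset set; sites
   flagged within the last 5 flagged seconds form the terminal set.
   Midline (z) electrodes never vote on laterality; A1/A2 carry left/right
   tags like scalp sites. Lateralized onset sites in both hemispheres ⇒
   SOZ "both hemispheres" and a generalized seizure; otherwise the SOZ is
   the single onset hemisphere and the seizure is focal. Terminal sites
   refine a unilateral verdict but never override the onset.

## Implementation notes

* **NumPy classifier.** The forward pass, backpropagation, Adam, inverted
  dropout and early stopping are implemented directly in NumPy.
  Convolutions run as k shifted GEMMs rather than an im2col copy (the copy
  dominated runtime at these layer sizes); max-pool gradients route through
  recorded argmaxes. The vectorized forward pass is verified against a
  nested-loop oracle to 1e-6, and all gradients were checked against
  central differences during development.
* **Filter realization.** 5th-order Butterworth applied forward–backward
  (zero phase, so spike timing is not shifted across window boundaries).
  The zero-phase effective response is the squared one-pass magnitude:
  order 5 gives ≈ −20.4 dB at 50 Hz and < 0.5 dB ripple across 2–30 Hz.
  A 4th-order design would only reach ≈ −16.9 dB at 50 Hz, short of the
  ≥ 20 dB stop-band attenuation this package asserts.
* **Resampling.** Polyphase rational resampling (89/128 for 256 → 178)
  with anti-aliasing; output length is exact by construction.
* **Standardization.** Per-window z-scoring with the population standard
  deviation is the default: it is the only mode applicable to a single
  detected second and makes the classifier amplitude-scale invariant.
  Per-column statistics frozen from a training split are available behind
  `PreprocessConfig(standardization="per_column")`. A flat window
  (σ = 0) maps to all zeros rather than erroring — post-ictal EEG can go
  flat and such seconds must remain classifiable.
* **SMOTE scope.** Default `train_only`: rebalancing happens inside each
  fold's training portion, so validation rows are untouched real rows.
  `train_plus_val` rebalances the whole 80 % pool before folding, matching
  protocols that apply SMOTE ahead of the split, at the cost of synthetic
  neighbours leaking into validation. Both are runnable; only the scope
  flag differs.
* **Early stopping.** Monitors validation loss with best-weight
  restoration and `min_delta = 1e-4`: an epoch counts as progress only if
  validation loss drops by more than that. On strongly separable synthetic
  data the loss otherwise keeps micro-improving for the full 200 epochs
  after the metrics have long saturated.
* **EDF.** Reading goes through `mne`; writing uses a minimal 16-bit EDF
  encoder in `io_formats` (per-channel physical min/max from the data, so
  the quantization step is (max − min)/65535). The mne reader doubles as
  an independent cross-check on the writer in the tests.
* **Checkpoints.** One `.npz` archive holds layer shapes, weights and the
  full preprocessing configuration, so detection always reproduces
  training-time preprocessing exactly.

## Synthetic data

The clinical multi-channel recordings this method targets are not
distributable, so `synthetic_eeg` generates both corpora with known ground
truth:

* **Background**: 1/f-shaped noise (slope 1) plus a 10 Hz alpha rhythm,
  normalized to zero mean and unit variance, scaled to 40 µV — a standard
  resting-EEG surrogate. Class variants 2/3 alter the variance scale
  (×1.5 / ×0.75); classes 4/5 use weak/strong alpha (eyes open/closed).
* **Ictal activity**: ~3 Hz spike-and-wave — a fundamental sinusoid with
  2nd/3rd harmonics and one sharp ~20 ms transient per cycle — normalized
  so that every ictal window's RMS is 1.1 × the configured gain (default 4)
  relative to unit-RMS background. Single-channel rows are band-limited to
  0.53–40 Hz, like the corpus they emulate.
* **Multi-channel recordings**: 21 named channels at 256 Hz; a propagation
  schedule assigns each seizing site an [onset, offset) interval; the
  ground-truth matrix marks every whole second covered by an interval
  (partial tail seconds round down, matching the 1-s non-overlapping
  windowing). The default scenario seizes at right-frontal sites at
  t = 10 s and spreads bilaterally 6 s later — deliberately after the 5-s
  onset window, since a "later spread" that falls inside the onset window
  would by definition not be an onset/spread distinction the 5-s rule can
  see.

What the generator does **not** emulate: eye-blink/EMG artifacts, volume
conduction between neighbouring channels, inter-patient variability,
non-stationary background, and realistic ictal evolution (chirps,
post-ictal suppression). Passing tests on this data therefore demonstrate
that the pipeline's machinery is correct and that the method recovers
planted spatio-temporal structure; they do not certify clinical
performance. On the real single-channel corpus (11,500 rows, obtainable
separately) the same protocol at the published hyper-parameters is expected
to land within about one percentage point of the published accuracy /
sensitivity / specificity.

## Laterality rule edge cases

The hemisphere rule is deliberately conservative: one lateralized onset
site per hemisphere suffices for "both hemispheres". A midline-only onset
raises an explicit indeterminate-laterality error instead of guessing.
The 5-s onset/terminal windows are configurable
(`analyze_matrix(onset_window_s=..., terminal_window_s=...)`).

## Problem sizes

The shipped tests and the acceptance script run the full protocol at 200
rows per class (1,000 windows, 80/20 split, 10-fold CV) and detection on a
35-s, 21-channel recording; these sizes exercise every code path while
keeping a complete run in minutes on one CPU. All randomness flows from
explicit seeds; identical seeds reproduce bit-identical synthetic data,
training histories and reports.

## Known limitations

* The DWT baseline's published reference feature set is under-specified
  upstream; the db4/4-level/5-statistic recipe here is a declared default,
  so baseline numbers are indicative, not a reproduction.
* The onset rule latches onto the first flagged second; a single spurious
  verdict before the true onset can shift the onset window. The classifier's
  specificity on matched synthetic data makes this rare, but noisy real
  recordings would warrant temporal smoothing, which is deliberately out of
  scope here.
* Only hemisphere-level localization is attempted; lobe-level inference
  beyond naming persistent sites, source imaging and MRI fusion are out of
  scope.
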