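# Methods

## Spectrogram frames

A recording (channels × samples, 256 S/s default) is processed per
channel in non-overlapping 1-s blocks. Each block is linearly detrended
(least-squares line removed), tapered with a periodic Hann window, and
Fourier-transformed; the amplitude spectrum (not power) is kept. A 1-s
block gives native 1 Hz spectral spacing; the analysis grid is 2 Hz, so
consecutive non-overlapping pairs of native bins — (4,5), (6,7), …,
(44,45) Hz — are averaged into one analysis bin labeled by the even
frequency. Band endpoints 4 and 44 Hz are both included, giving exactly
21 bins. Aggregating by pair-averaging (rather than decimating to the
even bins or halving the block length) keeps all the spectral energy in
the band while matching the 21-bin grid; it is the one place where the
target frame geometry admits more than one construction, and the choice
is isolated in `epoch_spectrum`.

A frame stacks 20 consecutive epoch spectra per channel:
`channels × 21 (freq) × 20 (time)`. Frames start at 0, 1, 2, … s — a
1-s sliding window over frame *starts*, while the epochs inside a frame
do not overlap — so a recording of T whole seconds yields
`min(max_frames, ⌊T⌋ − 19)` frames; 167 s gives the default cap of 148.
Frames are taken contiguously from the start of the recording.

Normalization: per (channel, frequency) cell, the mean and SD are
computed over all training frames and epochs; frames are z-scored with
those statistics. Cells with SD below 1e-8 are floored (a constant cell
maps to ~0) with a logged warning. Test data always uses training-set
statistics; inside cross-validation the normalizer is refitted per fold
on that fold's training frames only.

An optional amplitude-threshold epoch screen (`screen_epochs`) is
provided for real recordings; it is not part of the core pipeline and no
claim is made that it reproduces any particular artifact-rejection
protocol.

## Classifiers

All three architectures map a frame to two-class softmax probabilities
and are trained by minibatch SGD (Adam, learning rate 1e-3, batch 64 by
default) on frame-level cross-entropy. They are scikit-learn-style
estimators (`fit`/`predict_proba`/`get_params`) over a small numpy
engine (`spectnet.nn`) with hand-derived backpropagation; every layer's
backward pass is verified against finite differences in the test suite.
Given a fixed `random_state`, initialization, batching and dropout are
all drawn from one generator and training is bit-reproducible
single-threaded.

* **DCNN** — two convolution stages (8 then 16 filters, 3×3 kernels,
  'same' padding) each followed by max-pooling of width 2 along the
  *time axis only*, then two dense layers (64, 32 units) with dropout
  0.5, then the output layer: four hidden layers in all. Time-only
  pooling builds tolerance to when a burst occurs while keeping
  frequency position sharp — the frequency of a burst is the
  discriminative feature, its timing is not.
* **RNN** — the frame read as a 20-step sequence of per-epoch feature
  vectors (channels × 21 bins); three stacked LSTM or GRU cells of 32
  hidden units, dropout between cells, class logits from the final
  hidden state. The LSTM forget-gate bias starts at 1.
* **Shallow baseline** — one dense hidden layer (64 units, dropout) over
  the flattened frame.

Layer widths, kernel and pool sizes, dropout rate and the optimizer
schedule are configurable; the defaults above are the smallest stack
that solves the synthetic task robustly. Dropout is applied to dense
layers (and between recurrent cells), not inside convolutions. Training
aborts with a diagnostic as soon as the loss is non-finite.

## Leave-pair-out evaluation

Subjects, not frames, are the unit of inference. Each experiment holds
out one random subject per class; remaining subjects are balanced by
random replication (with replacement, uniform) of the smaller class, so
both classes contribute equally many subject slots and hence frames. A
replicated subject's frames enter the training set once per slot. The
normalizer and classifier see only training frames. Held-out subjects
are scored by averaging their frames' probability vectors; the
predicted class is the argmax, with an exact 0.5 tie resolved to the
first class index (documented, deterministic).

Over N experiments the summary reports mean, SD and standard error of
train/test frame accuracy and subject accuracy. With one test subject
per class, per-fold subject accuracy is 0, 0.5 or 1, and its mean over
folds equals the pooled proportion of correct subjects. The AUC is the
Wilcoxon–Mann–Whitney statistic — ties counted ½ — computed on held-out
subject scores pooled across folds, because a per-fold AUC on a single
subject pair is degenerate. N defaults to 50 in the CLI; training per
fold dominates runtime, so channel sweeps use fewer folds per channel.
Each channel in a sweep derives an independent seed from its label, so
results do not depend on sweep order.

## Synthetic data

The generator defines the conditions under which the pipeline is
validated; it has two levels.

**Spectrogram-level bursts.** A frame is background Gaussian noise
(SD 0.25) plus a Poisson number (mean 3) of 2-D Gaussian bumps per burst
family, clipped at zero. Defaults per burst: sigma 1 epoch in time × 2
Hz in frequency, unit amplitude; per-burst jitter — frequency additive
SD 1 Hz, width and amplitude multiplicative SD 0.2; time positions
uniform over the frame. The default two-class task plants 10 Hz bursts
(alpha-like, class A) against 6 Hz activity that is twice as wide in
time (slower, more persistent — class B), emulating spectral slowing.
Subject structure: each subject first draws its own burst parameters
around the class recipe, then every frame re-jitters around the subject
values; each jitter SD is split evenly in variance between the two
levels (sd/√2 each), so the total frame-to-frame spread matches the
configured jitter while frames within a subject stay correlated. This
correlation is exactly what makes subject-aware splitting necessary —
random frame-level splits would leak subject identity.

**Raw-signal level.** Each channel receives Poisson-timed bursts of a
sinusoidal carrier (random phase) under Gaussian amplitude envelopes,
plus white noise (SD 0.5) and 1/f-amplitude noise (scale 0.5). Class A
uses a 10 Hz carrier with short (0.5 s) envelopes at 0.6 bursts/s;
class B a 6 Hz carrier with long (1.5 s) envelopes at 0.4 bursts/s.
Defaults: 14 channels, 256 S/s, 167 s (→ 148 frames).

What the synthetic data does *not* emulate: volume conduction and
inter-channel correlation, non-stationary artifacts (eye blinks, muscle,
electrode drift), realistic alpha reactivity, or any cohort's actual
spectra — no generator parameter was fitted to clinical data. Passing
tests therefore demonstrate that the pipeline recovers planted
time-frequency structure under subject-correlated jitter and noise, not
that any particular clinical accuracy is attainable.

## Activation maximization

Prototype synthesis ascends the *raw output-node activation* (the class
logit) rather than the softmax probability, which saturates and kills
the gradient. Three standard regularizers keep the ascent out of
adversarial-noise directions, where the class probability is maximal
but the image is unstructured: the gradient is normalized to unit L2
per step (step size 0.2 in z-score units), the image decays toward zero
by factor 0.99 per step (suppressing unconstrained directions), and a
Gaussian blur of sigma 0.5 bins is applied over the (frequency, time)
plane each step. Without these, the ascent reaches probability 1.0 with
images whose dominant frequency is arbitrary; with them, prototypes are
stable across seeds. The returned image is the best-scoring iterate
(later iterates win ties), so its class probability never falls below
the initialization's.

The ascent runs in the normalized space the model was trained in. There
the image emphasizes *discriminative* cells: for two overlapping burst
classes these sit on the far flanks of each class's band (e.g., 12 Hz
and 4 Hz for 10-vs-6 Hz classes) — informative in its own right, but
not the planted frequency. De-normalizing with the training statistics
(`DreamImage.denormalized`) returns to amplitude units, where the
dominant frequency coincides with the class's planted burst frequency;
quantitative burst-frequency readings use the de-normalized image, as
one would read a displayed spectrogram. `dominant_frequency` resolves
exact ties to the lowest bin.

## Problem sizes and numerical choices

* Acceptance-scale runs use 20 subjects per class × 148 frames and 20
  leave-pair-out folds with 1,000 training steps per fold; on this task
  the loss plateaus well before that. Smaller supporting analyses
  (chance-level recovery under label permutation, prototype recovery,
  shallow-vs-deep ordering) use reduced subject/frame counts chosen so
  the property under test — which is scale-free in each case — is
  measured with adequate statistics.
* Chance-level checks compare deviations from 0.5 against 3 standard
  errors (empirical SEM over folds for accuracy; Hanley–McNeil for the
  pooled AUC).
* All randomness flows from explicit `numpy.random.Generator` seeds:
  generation, splitting, initialization, batching, dropout, dream
  initialization. Identical seeds give bit-identical results
  single-threaded.
* Degenerate inputs are rejected with specific errors: recordings
  shorter than one frame, sampling rates that cannot resolve 44 Hz,
  classes with fewer than two subjects, empty score lists, frame-shape
  mismatches.

## Known limitations

* The convolutional/recurrent architectures follow the published
  description at the level it is given (layer counts, pooling axis,
  cell counts and widths); exact filter counts and kernel sizes of the
  original networks are not public, so quantitative clinical results
  are not expected to transfer, and the clinical cohort itself is not
  reproducible here.
* The numpy engine is single-threaded and CPU-bound; it is sized for
  desk-scale experiments (thousands of frames), not large cohorts.
* EDF files can be read (via `mne`) but not written; portable outputs
  use HDF5.
* The WMW AUC is quadratic in the number of subjects scored — fine at
  cohort scales here.
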