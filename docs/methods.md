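# Methods

## Problem setting

`megdecode` implements a complete within-subject decoding analysis for
multichannel MEG epochs: five same-hand movement conditions (four movements
plus rest) are classified from 2-second sensor-space epochs centered on the
task onset, the decoder's weights are translated into physiologically
interpretable spatial and spectral patterns, and the resulting accuracies
are judged against properly calibrated chance levels. Because raw MEG
recordings of this kind cannot be redistributed, the package ships a
synthetic session generator that reproduces the statistical structure the
analysis relies on, with full ground truth, so that every stage — from
filtering to weight interpretation — is testable end to end.

## Synthetic sessions

A session consists of `n_classes * trials_per_class` epochs of
`n_channels x n_samples` (defaults: 5 x 60 epochs, 204 channels, 2 s at
500 Hz; analyses in this repository are typically run at 250 Hz, which
keeps the alpha/beta band far below Nyquist at half the compute).

**Class sources.** Each non-rest class k has a single oscillatory source: a
sinusoid at the class's center frequency (defaults 9, 11, 19, 25 Hz — two
alpha-range and two beta-range rhythms) with a fresh uniform random phase
per trial. Event-related desynchronization (ERD) is modeled by an amplitude
envelope equal to 1 before `erd_onset` (default −0.2 s, i.e. ~200 ms before
task onset) and `sqrt(1 − erd_depth)` afterwards, so that band *power*
drops by exactly `erd_depth` (default 0.5); the transition is a 100-ms
raised cosine to avoid spectral splatter. The source is projected into the
sensors through column k of a mixing matrix.

**Mixing matrix.** Sensor topographies are smooth random fields: white
noise over a fixed near-square 2-D sensor grid, convolved with a squared-
exponential kernel of correlation length `topography_smoothness` (default 2
grid units) and normalized to unit column norm. This stands in for the lead
field; no anatomical forward model is attempted. Note that independently
drawn smooth columns can correlate substantially by chance (|r| up to ~0.6
at 204 channels), which is itself realistic — neighboring movement
representations overlap — and bounds how cleanly any decoder's patterns can
isolate one class's topography.

**Noise.** Per-channel background noise is the sum of 1/f-spectrum noise
(spectral shaping of white noise, exponent 1.0, 50% of the noise variance)
and white sensor noise (the other 50%), scaled so that the class-signal
variance at each class's focal sensor is `snr` times the per-channel noise
variance (default snr 5). A spatially fixed, class-independent evoked-like
transient (Gaussian-windowed 3-Hz burst peaking 150 ms after onset) is
added to every trial; it carries no label information and stands in for the
visually evoked response common to all conditions.

**Accelerometers.** Two channels of white noise; in movement mode a
high-amplitude burst (instant attack, Hann decay, 0.3 s, 8-Hz carrier,
20x the noise amplitude) starts at the trial's true movement onset, drawn
from Normal(21.3 ms, 176.1 ms) around the cue and truncated so the burst
fits the epoch. Imagery and control sessions contain no burst. The instant
attack makes the injected onset recoverable to ±1 sample by threshold
detection, which pins down the onset-realignment contract exactly.

**Null sessions** use the identical background + evoked generative process
for every trial and assign labels independently of the data: any decoder's
accuracy is chance by construction. These emulate a passive-viewing control
in the limit where the evoked response is class-independent.

**What the generator does not emulate:** realistic forward fields and
sensor geometry, inter-trial nonstationarity, eye/cardiac artifacts, head
movement, spatially correlated background activity (background noise is
spatially independent per channel; spatial correlation enters only through
class sources and the shared evoked component). Passing tests therefore
demonstrate correctness of the algorithms and calibration of the
statistics, not performance on real recordings.

## Preprocessing

Continuous data are zero-phase filtered (Butterworth; low-pass of order 4
and, for a nonzero lower edge, a separate high-pass of order 2 — a single
band-pass with a 0.1-Hz edge at 1 kHz is numerically unstable) and
decimated by an integer factor with anti-aliasing. Epochs are half-open
sample slices `[onset + w0*sfreq, onset + w1*sfreq)`; each epoch is
standardized by one scalar mean and one scalar population SD pooled over
all of its channels and samples. Movement onsets are detected as the first
post-cue sample where the RMS magnitude across the two accelerometer
channels strictly exceeds 10x the population SD of that magnitude over the
pre-stimulus window; a sample exactly at threshold does not trigger (the
boundary has measure zero on real data, but a fixed convention is needed).

## The classifier

LFCNN: a compact CNN whose layers mirror the generative model of MEG.

1. spatial demixing `s_k = w_k^T x` (channels → K latent components);
2. one temporal FIR kernel per component (depthwise; no cross-component
   mixing — required for the per-component interpretation to be
   well-defined), "same" output length with TF-style asymmetric padding;
3. ReLU;
4. temporal average pooling, output length `floor((T − window)/stride)+1`;
5. dropout (training only), flatten in component-major order;
6. dense softmax readout.

Default hyperparameters: 32 latent components, kernel 32 samples, pooling
64/32, dropout 0.5, l1 3e-3 on the output weights, minibatch 50, 25 steps
per training epoch, Adam at 3e-4, early-stopping patience 10 (training
stops after `max(patience, 1)` consecutive epochs without a validation-loss
improvement and restores the best state). The forward pass, analytic
gradients and Adam are implemented in NumPy (float64); gradients are
checked against central finite differences to 1e-4 relative error. The l1
penalty is applied to the output weights only by default (`l1_scope="out"`),
which concentrates class evidence on few components; `"all"` extends it to
every weight. An optional ridge penalty on the demixing weights (`l2_dmx`)
is available: minimum-norm spatial filters are closer to covariance-optimal
extraction filters, whose projected patterns are cleaner, at no accuracy
cost on separable data.

Analyses in this repository typically run compact variants (e.g. 8 latent
components, kernel 32 at 250 Hz, pooling 32/16) whose pooled receptive
fields match the defaults in milliseconds; capacity well above the true
source count mainly slows training on synthetic data.

The baseline is an RBF-kernel SVM on standardized epochs flattened to
channel x time vectors, with a stratified 9-fold CV grid search over C in
1e-4 … 1e4.

## Evaluation

Trials are split into 10 stratified folds; the last is a fixed holdout test
set and each of the remaining nine serves once as the validation fold
(early stopping + reported CV accuracy) while the other eight train the
model. Confusion counts from the nine validation folds are summed and
row-normalized by true-class totals. Leave-one-subject-out training pools
all remaining sessions and holds out 10% (stratified) for early stopping.

Chance levels: theoretical `100/K` percent; the binomial threshold — the
smallest k with `P(X ≥ k) < alpha`, `X ~ Binomial(n, 1/K)`, as a
percentage of n (for n=300, K=4, alpha=0.001 this is 33%; for K=5 it
approaches 20% as n grows) — and the empirical level, the mean CV accuracy
of a decode run on control data. Accuracy comparisons across subjects use
a two-sided paired Student's t-test; zero-variance differences raise an
error rather than fabricating p=1.

Because early stopping selects the checkpoint by validation loss, reported
validation accuracies carry a small optimistic selection bias; on null
sessions with short training schedules the bias is well below the width of
the binomial band, which the 20-session null calibration verifies
empirically.

## Weight interpretation

* **Contributions** `c_kj`: the inner product between component k's pooled
  activations and its output weights for class j, averaged over validation
  epochs *of class j* (the class-conditional mean; an unconditional variant
  is available). The class bias is reported separately, so
  `sum_k c_kj + b_j` reproduces the mean pre-softmax logit exactly — an
  identity the tests assert to 1e-6.
* **Spatial activation patterns** `a_k = Sigma^T w_k`: the covariance
  projection of the demixing filters. Sigma is the pooled spatial
  covariance (per-trial mean removed) of the standardized session; using
  the whole session rather than a single validation fold gives a much
  better-conditioned estimate at 204 channels. Raw filter weights are *not*
  interpretable as topographies; the projection is what restores them.
* **Spectral fingerprints**: Welch PSD (1-s Hann windows, 50% overlap) of
  each component's latent time course averaged over validation epochs,
  multiplied binwise by the squared magnitude of the kernel's frequency
  response (kernel zero-padded to the PSD resolution), normalized to
  percent of its own total.
* **Class patterns**: per fold, `pattern_j = sum_k c_kj a_k` (and likewise
  for spectra), averaged across folds. Component sign is not identifiable,
  so patterns can cancel across folds; an optional correlation-sign
  alignment to the first fold is provided and off by default.

**Known limitation.** A discriminative spatial filter is not an extraction
filter: when two classes' topographies overlap, the trained filter for one
class deliberately contains a negative image of the other, and
`Sigma^T w` inherits that mixture. On synthetic sessions at snr 5 the
top-contributing component's pattern correlates with the true mixing column
at ~0.92 on average (over classes and seeds), but individual class/seed
combinations with strongly overlapping or same-band topographies can drop
to ~0.77. Fingerprint peaks are far more robust (exact to the 1-Hz bin in
all tested runs) because the kernel's frequency response is class-specific
even when the spatial filter is mixed.

## Spectral validation analyses

Global field power is the RMS across a picked channel cluster of the
trial-averaged signal, optionally after a zero-phase low-pass. TFRs use
Morlet wavelets (`mne.time_frequency.tfr_array_morlet`) with n_cycles =
f/2, averaged over trials and picked channels, expressed as percent change
from a baseline window per frequency, with 0.2 s cropped at each edge.
Band-power topographies band-pass filter the epochs, square, and average
within a window vs a baseline window per channel.

## Reproducibility

Every stochastic step takes a seed; the pipeline derives per-stage seeds
from one global seed via a stage-name-keyed map (`seed*1000003 +
crc32(stage)` mod 2^31), writes a manifest with config and SHA-256
checksums of all artifacts, and a rerun with the same config produces
byte-identical reports.

## Problem sizes used in the shipped analyses

The repository's reference analyses (see `megdecode.benchmarks` and
`scripts/acceptance.py`) use: ground-truth recovery on 204-channel,
300-trial sessions at 250 Hz, snr 5, three seeds, one train/validation
split per seed; null calibration on twenty 64-channel, 300-trial null
sessions at 200 Hz with a compact model and the full nested 9-fold CV per
session; and the classifier-ordering check on one 64-channel session at
snr 2 with nested CV for the LFCNN and a 9-point C grid for the SVM. These
sizes were chosen so each analysis completes in minutes on a single CPU
while keeping the conditions that matter (channel count, trial count, snr,
class structure) at study scale.
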