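# Methods

## Problem and data model

The package classifies 5-s photoplethysmogram (PPG) segments into JNC7
blood-pressure classes — normotension (NT), prehypertension (PHT),
hypertension (HT) — using the paired arterial-pressure (ABP) segment only to
derive the label. Records are 10 s at 125 Hz and are split into two 5-s
halves; a 125 Hz rate comfortably covers the 0–13 Hz band in which the
pipeline operates.

JNC7 staging is implemented as: HT if SBP ≥ 140 mmHg or DBP ≥ 90 mmHg, else
PHT if SBP ≥ 120 or DBP ≥ 80, else NT. The printed staging table ("120–139"
vs "> 140") leaves the open intervals (139, 140) and (89, 90) unassigned; we
close them on the hypertensive side, which matches the guideline itself, and
expose the strict `>` reading behind `strict_bounds=True`. SBP/DBP are read
as segment extrema (global max/min of the 5-s ABP segment); per-beat
averaging would be the natural alternative but extrema are what a
pulse-pressure-preserving generator pins exactly, and flat segments
(pulse pressure < 5 mmHg) are rejected as non-arterial.

## Synthetic cohort generator

The generator is a morphological emulator, not a hemodynamic model. A PPG
beat is the sum of three Gaussian bumps — systolic peak, tidal wave, dicrotic
wave — parameterized by fractional positions/widths of the beat period; the
tidal and dicrotic widths are fixed multiples (1.6×, 1.4×) of the systolic
width to keep the parameter family minimal. The class templates encode the
established hypertensive morphology:

* **NT** — distinct tidal wave (amplitude 0.40 at 45% of the period) and a
  pronounced dicrotic wave (0.35 at 68%); symmetric systolic bump.
* **PHT** — tidal wave grown and migrated toward the main wave; moderately
  steepened descending branch.
* **HT** — tidal wave merged with and exceeding the main wave (amplitude 1.05
  at 32%), giving the rounded hypertensive main wave; descending branch
  steepened by narrowing the systolic bump's right flank 6×; dicrotic wave
  nearly absent.

The steep HT descending flank is what places hypertensive spectral energy at
higher instantaneous frequency, the discriminative feature the spectrogram
representation is built to expose. A consequence worth stating: the clean HT
beat train carries roughly −19 dB of its power above 13 Hz at the fastest
heart rates (NT about −31 dB), so the 0–13 Hz spectrogram ceiling captures
≥ 98% — not 100% — of clean-signal energy; the 0.4–8 Hz bandpass removes the
excess before imaging.

Cohort-level defaults are the study conditions: heart rate uniform in
0.8–2 Hz with ±5% beat-to-beat period jitter (avoids degenerate line
spectra), additive white noise of 0.05 systolic amplitudes, sinusoidal
baseline drift of amplitude 0.5 at 0.15 Hz (below the 0.4 Hz filter edge, so
removable by construction). Per-class SBP/DBP are drawn uniformly from
disjoint JNC7-consistent boxes (NT 100–119/60–79, PHT 120–139/80–89, HT
140–180/90–110), so no draw is ambiguous. ABP beats within a record share one
amplitude profile (only the period jitters) and the record is rescaled so its
global max/min equal the drawn SBP/DBP exactly — hence every full-beat 5-s
segment reproduces the record's pressures and the label round trip is exact.
`exact_counts` optionally replaces the multinomial class draw with exact
per-class counts (shuffled order) for experiments that need balanced cohorts
at small n.

What the generator does **not** emulate: pulse-transit-time physics, beat-to-
beat amplitude variability, sensor saturation/motion episodes, respiratory
modulation, arrhythmia, or any within-class correlation between heart rate
and pressure. Passing tests on this cohort therefore demonstrate that the
pipeline recovers class structure that is encoded in beat morphology; they do
not certify performance on clinical recordings.

## Signal conditioning

Bandpass: Butterworth order 4, applied forward–backward (`sosfiltfilt`) for
zero phase — phase distortion would deform the derivative channels. The order
is a design choice (standard physiological practice); reflection padding of
5 s bounds the 0.4 Hz edge's transient. Normalization is per-segment min–max
to [0, 1]. Derivatives (PPG′, PPG″) are central finite differences scaled by
the sampling rate, one-sided at boundaries, and are computed **after**
denoising, since differentiation amplifies exactly the noise EEMD removes.

## EMD / EEMD

Sifting follows the canonical loop: subtract the mean of the cubic-spline
envelopes through the local maxima and minima until the Cauchy criterion
SD = Σm²/Σh² < 0.2 (Huang's standard threshold) and the IMF conditions hold
(|#extrema − #zero-crossings| ≤ 1, envelope-mean magnitude ≤ 10% of the peak),
capped at 50 iterations; IMF extraction stops when the remainder has fewer
than two maxima or minima (the residue) or at 10 IMFs. The two edge extrema
are mirrored across each endpoint before spline fitting to suppress end
swings. Because each IMF is literally subtracted from the running remainder,
sum(IMFs) + residue reproduces the input to machine precision regardless of
where sifting stops.

EEMD adds white Gaussian noise of 0.2 input standard deviations (default) to
each of 100 ensemble members (deterministic per-member sub-seeds spawned from
one seed), decomposes each, and averages IMF k across members, padding
shorter decompositions with zeros; the residue is redefined as input minus
the averaged IMFs so the reconstruction identity survives averaging. With
ensemble size 1 and zero noise EEMD reduces exactly to EMD.

Denoising reconstructs from IMFs whose amplitude-weighted mean instantaneous
frequency lies in 0.4–13 Hz, aligning the selection rule with the bandpass
edge and the spectrogram ceiling rather than with fixed IMF indices, which
would be fragile across heart rates.

## Hilbert spectra

Instantaneous attributes come from the FFT-based analytic signal. Two
numerical safeguards matter in practice: (1) both ends are extended by 1 s of
AR(32) (Yule–Walker) extrapolation before the transform — the FFT assumes a
periodic window, and for tones with a non-integer cycle count the leakage
otherwise modulates amplitude and frequency across the entire segment (up to
10% at 1.5 Hz on a 5-s window); (2) the phase-difference frequency is passed
through a 5-sample median filter (unwrap glitches) and a quarter-second
moving average (residual leakage ripple). With both, pure-tone frequency is
recovered within 1% across 0.8–6 Hz and chirp frequency is monotone.

The spectrum accumulates **amplitude** (not squared energy) on a
130 × 625 grid (0.1 Hz × one sample) over 0–13 Hz × 0–5 s; samples whose
instantaneous frequency leaves the band are discarded, so binned mass never
exceeds summed amplitude. Rendering to the 1247 × 770 raster uses
nearest-neighbour index mapping — the image is a data raster, and
nearest-neighbour preserves the cell ordering exactly (monotone rendering) —
followed by linear scaling of the maximum to 255. Per-channel max scaling
makes the image invariant to overall amplitude, which is also why the
classifier cannot rely on absolute signal amplitude.

## PPG+ images, augmentation, splits

R/G/B = spectrograms of (PPG, PPG′, PPG″); the PPG-only control zeroes G and
B. Training augmentation is a seeded random aspect-ratio crop (area 0.7–1.0,
log-uniform aspect 3/4–4/3), horizontal flip with p = 0.5, then a center crop
to square; evaluation uses the deterministic center-crop path only. Network
inputs are 224 × 224, scaled to [0, 1] and standardized with the conventional
pretrained-backbone channel statistics (mean 0.485/0.456/0.406, std
0.229/0.224/0.225).

Splits are stratified by class at 7:3 with k = 5 folds over the training
rows. Both 5-s halves of a record always land on the same side and in the
same fold: the halves are near-duplicates, and letting them straddle the
split would leak test information into training. Per-class train counts use
largest-remainder allocation and folds are filled by global round-robin, so a
balanced 100-segment manifest splits exactly 70/30 with five 14-segment
folds.

## Classifier

Backbones are declarative layer stacks in a small numpy framework (im2col
convolutions, analytic shape/parameter/MAC accounting, backpropagation and
Adam for the trainable layers). AlexNet's head adaptation removes the
1000-way layer and appends dropout (default p = 0.6) plus a fresh 4096 → 2
layer: 57.01 M trainable parameters, and 0.71 GMAC per 3 × 224 × 224 forward
pass under the stated MAC convention (convolution and affine
multiply-accumulates only; bias, activations, pooling and normalization
excluded). ResNet18/34 replace the final layer with a fresh 512 → 2 layer.
Pretrained ImageNet weights are not bundled: `pretrained=True` is accepted
for interface compatibility but initializes from the seed with a warning, so
the large backbones serve architecture accounting and forward-pass checks,
not transfer learning.

`small_cnn` is the trainable desk-scale model: per-sample input
standardization, an 8× average-pool downsampler (224 → 28), three
conv(3×3)/ReLU/max-pool blocks (8, 16, 32 channels), then 288 → 64 → 2 affine
layers with dropout. The input-standardization layer is load-bearing: after
the fixed channel standardization the sparse spectrogram tensors are
dominated by a constant background, and without per-sample centering the
first convolution's activations are so ill-conditioned that short training
runs collapse to the class prior.

Training is softmax cross-entropy with Adam, batch size 16, fully seeded
(weight init, batch order, dropout masks) and single-threaded. The reference
protocol is learning rate 0.001 for 25 epochs per fold; the desk-scale trials
in the tests and acceptance script train `small_cnn` at 0.003 for 10 epochs —
a tiny network making ~60 optimization steps needs the larger step size, and
0.001 was tuned for AlexNet-scale fine-tuning. The per-fold estimator seed is
independent of the fold id, so fold-averaged metrics are invariant to fold
relabeling.

Trials are binary: NT vs HT, NT vs PHT, (NT+PHT) vs HT. The positive class is
NT (or the pooled non-hypertensive group), so TPR reads as "fraction of
normotensive segments recognized" and TNR as hypertensive specificity.
Metrics at threshold 0.5: F1 (positive class), TPR, TNR, and ROC by explicit
threshold sweep over the unique scores (ties advance diagonally in one step),
with trapezoidal AUC; the sweep's AUC equals the normalized Mann–Whitney U
statistic, which the tests verify against an independent implementation.

## Problem sizes and determinism

The default end-to-end experiment used by the tests and the acceptance script
is 60 records (120 segments), exactly class-balanced NT/HT, noise-free, EEMD
ensemble size 8, spectrogram IMFs from plain EMD of the EEMD-denoised signal,
5-fold cross-validation at 10 epochs — about two minutes on one CPU. The
library defaults remain ensemble 100/25 epochs. Every stochastic step derives
from explicit seeds; reruns are bit-identical, and the pipeline caches the
image-building stage under a hash of the generating configuration.

## Known limitations

* EMD end effects are handled by mirrored extrema and AR extension, not by
  the (more elaborate) boundary schemes of some reference implementations;
  very short segments (< 2 beats) are not siftable and become residue.
* BatchNorm runs in inference mode only; ResNets are therefore not trainable
  in this framework (by design — they serve accounting and forward checks).
* The generator's class signal lives entirely in beat morphology; real
  cohorts add inter-patient variability no synthetic test can certify
  against.
* Augmentation is implemented and tested but the desk-scale trials train on
  the deterministic path; at 120 samples the crop jitter costs more in
  signal than it buys in invariance.
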