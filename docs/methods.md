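# Methods

`usvkit` implements a complete analysis chain for mouse ultrasonic
vocalization (USV) repertoires: syllable detection from ultrasonic audio,
fixed-size syllable spectrogram images, a variational-autoencoder (VAE)
latent embedding, kernel two-sample statistics for repertoire comparison,
and peri-stimulus vocal-rate metrics.  Everything is exercised end to end on
a synthetic vocalization generator with ground-truth annotations, so the
whole chain is testable without recorded audio.

## Synthetic vocal sessions (`usvkit.synth`)

Syllables are rendered as frequency-modulated tones.  The instantaneous
frequency follows a linear or half-cosine trajectory between `f_start` and
`f_end` (both confined to 25–120 kHz), optionally with an instantaneous
frequency step ("jump") partway through; the waveform phase is the
cumulative integral of the instantaneous frequency, so jumps change the
trajectory without a broadband click.  A Tukey taper (default 10% per edge)
shapes the envelope.  Audio is generated at 250 kHz.

A recording condition is a distribution over syllables plus a timing
process: per-syllable fields are independent truncated Gaussians, and onsets
follow a renewal process with a hard minimum gap (default 50 ms) plus an
exponential tail whose mean is derived from the target syllable rate
(default 2 s⁻¹).  White background noise sits ~30 dB below the mean
syllable RMS by default.

Default syllable statistics — duration 50 ± 12 ms, start frequency 70 ± 3
kHz, sweep extent ~8 ± 4 kHz, 20% jump probability — are chosen to resemble
adult female-directed USVs while keeping sweep rates below ~500 kHz/s.
Faster sweeps smear energy across many STFT bins within one 4.1 ms analysis
window and defeat any single-bin tonality measure; with these defaults the
detector below accepts ≥ 95% of rendered syllables, which is a design
requirement of the generator (the detection thresholds are fixed; the
generator is calibrated to produce calls those thresholds are meant for).

Amplitudes (default 0.08 ± 0.015 linear units) are calibrated so that
syllable log-magnitude spectrogram values land mid-way inside the fixed
clip window used for imaging (see below): a 0.08-amplitude tone yields a
peak log-magnitude of ≈ −3.2 under the STFT convention used here.

A two-condition dataset renders one session of each condition per mouse,
with condition B a shifted copy of condition A: amplitudes multiplied by
`amplitude_gain` and the mean sweep extent widened by `bandwidth_delta_hz`.
The standard shifted dataset uses gain 2 and 20 kHz — "louder calls with
wider frequency bandwidth" — and the standard null dataset uses no shift.

What the generator does **not** emulate: harmonic stacks, nonlinear
phenomena (subharmonics, deterministic chaos), reverberation, microphone
directionality, or overlapping callers.  Passing tests therefore show that
the analysis chain recovers distributional shifts of FM-tone repertoires at
realistic SNR; they do not certify performance on noisy colony recordings.

## Syllable detection (`usvkit.segment`)

Spectrograms use a Hann window with `nperseg=1024`, `noverlap=512` (hop
2.048 ms, resolution ≈ 244 Hz at 250 kHz) and natural-log magnitude floored
at 1e-12.  Frame times are window centers; segments are half-open
`[onset, offset)` in seconds.

Detection follows the classic whistle-detector recipe with the standard
USV thresholds: a frame is a candidate when its 25–120 kHz band power
exceeds a robust noise floor (median + 5·MAD over frames) **and** its
spectral purity exceeds 0.3.  Contiguous candidates are grouped; groups
separated by less than the 30 ms minimum inter-syllable interval are merged
(merging, rather than discarding the follower, keeps call bouts intact).
A group is accepted iff duration ≥ 5 ms, mean peak frequency > 45 kHz,
mean purity > 0.3, and spectral discontinuity < 0.85.

Because the classical threshold names do not pin down formulas, this
package defines them explicitly and documents the choice:

* **spectral purity** of a frame = power of the single peak bin / total
  in-band power (a Hann-windowed on-bin tone scores 2/3; broadband noise
  scores ≈ 1/#bins);
* **spectral discontinuity** of a segment = fraction of consecutive frame
  pairs whose peak-frequency step exceeds 10 kHz (smooth sweeps ≈ 0, noise
  ≈ 1), bounded in [0, 1] so the 0.85 threshold applies directly.

On clean synthetic sessions the detector achieves precision 1.0, recall
≥ 0.95, and mean onset error ≈ 0.6 ms (under one frame hop); white-noise
recordings yield zero detections (the purity gate rejects every frame).

## Syllable images (`usvkit.preprocess`)

Each syllable span is excised and transformed with the same STFT settings,
clipped to log-magnitude window [−5.0, −1.5], affinely mapped to [0, 1],
cropped to 30–110 kHz, and bilinearly interpolated onto a 128×128 grid.
The time axis is stretched so every syllable, 5 ms or 150 ms, fills all 128
columns; the frequency axis is linear in Hz (no mel warping); no
per-syllable renormalization is applied, so relative loudness is preserved
in pixel brightness.  The clip window only makes sense under a fixed gain
convention — here the STFT magnitude convention above plus the generator's
amplitude calibration.

## VAE latent embedding (`usvkit.vae`)

The VAE maximizes the usual evidence lower bound with a diagonal-Gaussian
encoder q(z|x), a standard-normal prior, and a fixed-scale Gaussian
likelihood (σ_obs = 0.1) on a sigmoid-bounded decoder output.  The
implementation is pure NumPy with hand-derived gradients and Adam
(lr 1e-3); all randomness (initialization, shuffling, reparameterization
noise) derives from one seed, so training is bit-reproducible on a machine.
The decoder output bias is initialized to the logit of the mean training
image, so the model starts at the mean-image baseline and any training
strictly improves on it.

Two modes are provided.  `linear_fast` (default) has no hidden layers: the
encoder/decoder are affine maps on the flattened image.  It trains on 2,000
images in well under a minute on one CPU and is used for every test and
replicate experiment.  `mlp` inserts ReLU hidden layers (default one of
256 units) for higher-fidelity reconstructions at higher cost.

**Effective dimensionality.**  Two criteria are exposed: the count of
latent coordinates whose average posterior variance falls below 0.5
(a collapsed coordinate reverts to the prior's unit variance), and the
number of principal components of the posterior means needed for 99% of
variance.  A caveat observed in practice: with a *linear* decoder on the
nonlinear image manifold, every latent projection contributes to
reconstruction, so the posterior-variance criterion does not prune
dimensions (all ~0.15), and the latent variance spectrum is dominated by
the brightness (amplitude) direction.  The package therefore treats
effective dimensionality as descriptive, not as a calibrated estimate of
the number of generative factors.

## Repertoire statistics (`usvkit.stats`)

**MMD.**  Squared maximum mean discrepancy with RBF kernel
k(a,b) = exp(−‖a−b‖²/2σ²).  The unbiased U-statistic (diagonal terms
excluded) is the default for comparisons — its null expectation is zero —
and the nonnegative biased V-statistic is available.  σ defaults to the
median pairwise distance of the pooled sample ("median heuristic").  Within
one mouse, a single bandwidth pooled over that mouse's syllables is reused
for both of the mouse's comparisons so they share a kernel scale.

**Within-session baseline.**  Repertoire variability expected *without* any
condition change: MMD between the first and second temporal halves
(split at ⌈n/2⌉) of the reference-condition session.

**Paired comparison.**  Per mouse, cross-condition MMD vs the half-split
baseline; a two-sided Wilcoxon signed-rank test on the paired differences.
W is the smaller rank sum.  Mode `auto` (default) uses exact enumeration of
the 2ⁿ sign assignments for n ≤ 25 without ties — measured type-I error
3% at α = 0.05 on 100 zero-shift replicates — and the continuity-corrected
normal approximation z = (W − n(n+1)/4 + 0.5)/√(n(n+1)(2n+1)/24) otherwise
(the cc approximation is conservative at n = 15; its null rejection rate
was 0 of 100).  A Mann-Whitney U test (exact for small tie-free samples) is
provided for unpaired group contrasts.

**Shift-vector consistency.**  Each mouse's repertoire shift is the
difference of mean latents between conditions; the test statistic is the
mean pairwise cosine similarity of these vectors across mice.  The null
permutes condition labels *within each mouse* (the finest exchangeable unit
under no condition effect), preserving per-condition counts, and the
p-value follows the add-one permutation rule
p = (1 + #{null ≥ observed})/(1 + n_shuffles).

**Condition information.**  Stratified five-fold cross-validation; within
each fold the majority class is subsampled to the minority count (seeded)
in both training and held-out sets, making the base rate 1 bit; a
standardized L2-regularized linear logistic model (C = 1) is fit and
bits = 1 − mean held-out cross-entropy (log₂), floored at zero.  On
label-shuffled data the estimate is ≈ 0; on widely separated classes ≈ 1.

**UMAP.**  Two-dimensional projections for visualization are delegated to
`umap-learn` with a fixed `random_state`.

## Peri-stimulus metrics (`usvkit.events`)

USV onsets are aligned to optogenetic stimulus epochs.  All bins are
half-open, so an event exactly at laser onset counts in the first
post-onset bin.  The PSTH (default window −2 to +6 s, 0.2 s bins — the bin
width is a package choice) reports across-trial mean rate and s.e.m. and
integrates back exactly to the mean per-trial count.  Latency to first USV
is scored within a response window defaulting to stimulus duration + 1 s,
since elicited bouts often outlast the stimulus.  The pre/laser/post metric
counts USVs in [−1, 0), [0, 1), [1, 2) s around onset and divides each by
the pre count; trials with zero pre-laser USVs cannot be normalized and are
excluded (and counted).  Place preference is the fraction of the 20-min
test spent in the stimulated side, computed over the observed occupancy
samples with a warning if coverage is incomplete.

## Replicate experiments and problem sizes

The standard **recovery experiment** is 15 mice × 2 conditions × ~200
syllables (100 s sessions at 2 s⁻¹), images rendered per annotated
syllable (the detector is validated separately and kept out of this loop),
a `linear_fast` VAE (latent 32, 15 epochs on a 2,000-image subsample), and
1,000 shuffles.  Across seeded replicates the pipeline reports
cross-condition MMD > baseline for ≥ 12/15 mice with signed-rank p < 0.05,
shuffle-test p < 0.01, and > 0.1 bits of condition information.

The **null calibration** uses 100 zero-shift replicates at the
annotation-feature level: the repertoire points fed to the statistics are
each syllable's realized generator features (duration, endpoint
frequencies, sweep extent, amplitude, jump size) rather than VAE latents.
This isolates the calibration of the statistics themselves from VAE
training cost; the statistics under test are byte-identical to the ones
used on latents.

## Known limitations

* FM-tone synthesis only; no harmonics or noise-burst call types.
* The purity/discontinuity formulas are documented stand-ins sharing the
  classical thresholds' semantics; other detectors' scores are not
  numerically comparable.
* The `linear_fast` VAE underfits fine spectro-temporal detail by design;
  the `mlp` mode trades runtime for fidelity.  Neither estimates the
  number of generative factors reliably (see effective dimensionality).
* Stretching all syllables to a fixed 128-column width discards absolute
  duration from the image; duration re-enters the analysis only through
  the metadata.
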