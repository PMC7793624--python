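# usvkit

Analysis of mouse ultrasonic vocalization (USV) repertoires: syllable
detection from ultrasonic audio, VAE latent embeddings of syllable
spectrograms, kernel two-sample statistics for repertoire comparison, and
peri-stimulus vocal-rate metrics for optogenetic experiments — with a
synthetic vocalization generator so the whole chain runs and is tested
without any recorded data.

## Who this is for

Researchers quantifying mouse vocal behavior: does a manipulation (an
optogenetic stimulus, a social context change) shift an animal's vocal
repertoire beyond its natural within-session variability, and is the shift
consistent across animals?  And how does vocal *rate* respond around a
stimulus?

## The analysis

1. **Detection.**  Syllables are detected from a Hann STFT spectrogram
   (`nperseg=1024`, `noverlap=512` at 250 kHz) by the classic whistle
   recipe: frames with in-band (25–120 kHz) power above a robust noise
   floor and spectral purity > 0.3 are grouped, groups closer than 30 ms
   are merged, and segments are kept iff duration ≥ 5 ms, mean peak
   frequency > 45 kHz, purity > 0.3 and spectral discontinuity < 0.85.
2. **Imaging.**  Each syllable becomes a 128×128 image: log-magnitude
   clipped to [−5, −1.5] and rescaled to [0, 1], cropped to 30–110 kHz,
   time-stretched onto 128 columns.
3. **Embedding.**  A variational autoencoder maximizes
   ELBO = E_q[log p(x|z)] − KL(q(z|x) ‖ N(0, I)) and each syllable is
   summarized by its posterior mean z ∈ R^d.
4. **Repertoire statistics.**  For each mouse, the squared maximum mean
   discrepancy MMD²(A, B) with an RBF kernel (median-heuristic bandwidth)
   measures the distance between condition repertoires in latent space; a
   *half-split baseline* — MMD between the first and second halves of the
   reference session — measures within-session variability.  A Wilcoxon
   signed-rank test compares the pairs across mice; a within-mouse label
   shuffle test asks whether per-mouse shift vectors align across mice
   (mean pairwise cosine similarity); a five-fold class-balanced logistic
   regression reports the condition information in bits; UMAP renders the
   latent space in 2-D.
5. **Event metrics.**  USV-rate PSTHs around stimulus onsets, per-trial
   first-call latencies, pre/laser/post counts normalized by the pre-laser
   count, and place-preference scores.

See `docs/methods.md` for the model details, parameter defaults, and the
design choices behind the purity/discontinuity definitions.

## Worked example

Simulate 15 mice, each recorded in a reference condition (A) and a shifted
condition (B) whose calls are twice as loud with 20 kHz wider sweeps, then
run the full image → VAE → statistics chain:

```python
from usvkit.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_mice=15, session_duration=100.0, seed=42, n_shuffles=1000)
m = run_pipeline(cfg)
pc = m["paired_comparison"]
print(f"syllables analysed : {m['n_syllables']}")
print(f"paired MMD test     : W = {pc['W']:.0f}, p = {pc['p']:.2e} "
      f"(cross > baseline for {pc['n_cross_greater']}/15 mice)")
print(f"shift consistency   : mean cosine = {m['shuffle_test']['observed_mean_cosine']:.2f}, "
      f"p = {m['shuffle_test']['p']:.2e}")
print(f"condition information: {m['condition_information_bits']:.2f} bits")
```

prints

```
syllables analysed : 6028
paired MMD test     : W = 0, p = 6.10e-05 (cross > baseline for 15/15 mice)
shift consistency   : mean cosine = 0.99, p = 9.99e-04
condition information: 0.69 bits
```

Reading the output: every mouse's cross-condition repertoire distance
exceeds its within-session baseline (W = 0 means all 15 paired differences
point the same way; the exact signed-rank p is the smallest attainable at
n = 15 apart from 2/2¹⁵).  The per-mouse shift vectors are almost perfectly
aligned (cosine 0.99), and the shuffle p of 1/1001 is the minimum under
1,000 shuffles.  The latents carry 0.69 of the 1 bit of condition identity.
On a zero-shift dataset all three statistics are null-calibrated (rejection
rates near 5%, ~0 bits).

The same pipeline is available from the shell:

```sh
usvkit demo --seed 42 --outdir out/        # full pipeline + manifest.json
usvkit synth --duration 60 --outdir sess/  # one synthetic session (WAV + CSV)
usvkit segment sess/session.wav --out segs.csv
```

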