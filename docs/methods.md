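# Methods

`ecogspeech` reimplements, end to end, an offline study of continuous overt-speech
decoding from electrocorticographic (ECoG) activity with linear methods: vocoder
analysis/synthesis of the acoustic target, spectral neural features, cross-speaker
articulatory transfer by dynamic time warping (DTW), five linear decoders compared
under direct and indirect (articulatory) decoding paradigms, and a cross-validated
statistical evaluation. The patient recordings such a study rests on cannot be
redistributed, so the package is driven by a synthetic paired-corpus generator with
known ground truth; this note records the models, the parameter choices that
matter, and what the synthetic results do and do not establish.

## Speech representation (vocoder)

Audio is represented by a source–filter split at a 100 Hz frame rate:

* **Mel cepstrum** `c_0..c_24`: order-24 cepstrum of the log-amplitude spectrum on
  an all-pass-warped frequency axis (`alpha = 0.455`, the standard choice
  approximating the mel scale at 22,050 Hz). Analysis uses Blackman windows of 400
  samples, 1,024-point FFTs, a 220-sample frame shift (native rate ~100.23 Hz,
  resampled to exactly 100 Hz by shape-preserving pchip interpolation), and a
  periodogram floor of 1e-4. Two deviations from a textbook periodogram cepstrum
  were needed for a stable envelope estimate: the periodogram is smoothed across
  frequency (9 bins, about one harmonic spacing) so the cepstrum tracks the
  envelope rather than the source comb, and averaged over 3 adjacent frames
  (Welch-style) because a 400-sample window holds only 1–2 pitch periods at low F0.
* **F0**: one value per frame, 0 when unvoiced, constrained to [80, 300] Hz.
  The estimator is a normalized-autocorrelation tracker (pluggable by design;
  any estimator with the same constraint is acceptable) with parabolic peak
  refinement, an energy gate on the frame centre, nearest-neighbour resampling to
  100 Hz (discontinuities must survive), and removal of voiced runs shorter than
  50 ms.
* **Synthesis**: per 220-sample frame the truncated cepstrum is expanded to a
  linear-frequency amplitude response (same `alpha`) and applied to the excitation
  spectrum by windowed overlap–add; the excitation is an impulse train at the
  reconstructed pitch period `fs/F0` when voiced and white noise when unvoiced.
  Output is peak-normalized and set to −20 dBFS loudness with the gain capped so
  the peak never exceeds full scale (a limiter; hard clipping audibly and
  measurably corrupts the re-analysis).

Speech activity is detected from the Hilbert envelope smoothed with a 100 ms
moving average, thresholded at 10% of its per-sentence maximum; segments shorter
than 50 ms are dropped, then segments closer than 100 ms are merged (in that
order — a merged segment cannot be shorter than 50 ms).

## Neural features

Per electrode, 21 features on the same 100 Hz grid: short-time periodogram power
(200 ms Hamming window, 10 ms shift, symmetric signal padding) averaged within
10 Hz bands from 0 to 200 Hz, plus the raw signal band-passed 0.5–5 Hz. A
72-electrode montage therefore yields 1,512 features. The common median reference
subtracts the across-channel median per sample (more outlier-robust than the
mean); it is idempotent. The 0.5–5 Hz filter is applied with 3 s of reflection
padding: its 0.5 Hz edge rings for longer than a short sentence, and the default
transient handling contaminates the whole output.

Decoding aligns neural windows with targets through a delay `tau` and a symmetric
context of an odd number of frames. The window predicting target frame `t` spans
`t + tau - k ... t + tau + k`; negative delay therefore reads from the neural
past (a 210 ms context with −100 ms delay spans `[t-200 ms, t]`). Even nominal
contexts are promoted to odd frame counts (50 ms → 5 frames, 110 ms → 11,
210 ms → 21). Edge frames replicate the sentence boundary so correlations are
computed over entire sentences.

## Articulatory transfer

Reference-speaker EMA (9 sensors × 3-D at 100 Hz) is projected per sensor onto
its first two principal axes after dropping the two lip-corner sensors
(latero-medial movement only), giving 14 midsagittal features. For each sentence
pair the DTW feature vector has 27 values: the 25 mel coefficients divided by the
sentence's max |c0|, F0 divided by its sentence maximum, and a 0/1 speech flag;
speech and voiced runs under 50 ms are zeroed first. Both tracks are resampled to
the patient's length (pchip with point-symmetric padding, which preserves linear
trends at the boundaries) and aligned by dynamic programming with steps
{(1,0),(0,1),(1,1)}, ties preferring the diagonal. The sample-wise cost is the
**sum of squared differences** (no square root) — implemented exactly as that,
with an optional square-root variant for sensitivity checks. Feature groups are
weighted equally. Reference EMA is carried through the path by averaging the
reference frames mapped to each patient frame ("last match" selectable).

## Linear decoders

All five decoders share one pipeline, fitted on training folds only:
z-score (features and targets) → optional delay → optional PCA of the neural
features → temporal context concatenation → linear weights. PCA is computed
before context concatenation; PLS reduces after context as part of the
regression. Zero-variance features get unit sd and map to an exact 0 so
dimensionality is stable across folds.

* **OLS** — minimum-norm least squares (`numpy.linalg.lstsq`), warning on rank
  deficiency.
* **Ridge (L-curve)** — eigendecomposition path over 25 log-spaced strengths
  1e−4…1e4; corner = maximum finite-difference curvature of the smoothed
  (log residual norm, log solution norm) curve; a flat curve (noise-free,
  well-posed) falls back to the smallest strength.
* **Ridge (CV)** — the same grid, strength minimizing inner 5-fold validation
  MSE summed over outputs.
* **Ridge (CV per output)** — the CV procedure selected independently per
  output column.
* **PLS** — PLS2 with a shared latent space, NIPALS iterations run in
  covariance space (deflating X'X and X'Y; algebraically identical to score-space
  NIPALS, verified against scikit-learn to 1e−6), max 500 iterations,
  tolerance 1e−6; exposed as an equivalent weight matrix so all five decoders
  are interchangeable.

## Articulatory-to-acoustic synthesizer

A feedforward tanh network maps 10 past + current + 1 future EMA frames
(12 × 14 = 168 inputs) to the 25 mel coefficients of the current frame (10 ms
look-ahead only). Defaults: 3 hidden layers of 512 units, 25% dropout,
mini-batches of 32, Adam (1e−3; 1e−4 when fine-tuning, to preserve the
pretrained structure), early stopping with patience 20 on a 10% validation
split of an 80/10/10 frame-level random split, best-epoch weights restored.
Inputs and targets are z-scored with training-split statistics inside this
module; fine-tuning inherits the pretraining normalization so transferred
weights see inputs on the same scale, validates on whole held-out sentences
(frame-level random splits leak through within-sentence autocorrelation on
the small decoded-trajectory corpora used for adaptation), and returns a new
network (the input network is never modified). Implemented as a compact numpy MLP so training is
bit-deterministic given a seed.

## Evaluation framework

Sentences are split into 10 folds, stratified by speaking condition and seeded;
every sentence is tested exactly once. Direct decoding predicts mel (25) and F0
(1, always decoded directly) with separate decoder fits — a shared PLS latent
space across heterogeneous targets would couple them, and separate fits leave
OLS/ridge results unchanged. Indirect decoding predicts the 14 articulatory
features, decodes them for *all* sentences with the fold's decoder, fine-tunes
the pretrained synthesizer on the training folds' (decoded EMA → patient mel)
pairs, and evaluates predicted mel on the test fold; the non-fine-tuned variant
uses the pretrained net as-is and is scored against the reference speaker's mel
warped onto the patient's timing by DTW (it was never trained to produce the
patient's voice). Metrics are Pearson r and MSE per sentence and feature;
zero-variance columns score r = 0 with a degenerate flag.

Chance levels permute neural feature frames uniformly across the whole corpus
(once per experiment, seeded) and rerun the identical pipeline. Real-vs-chance
contrasts use a two-sided Wilcoxon signed-rank test (exact sign-enumeration
distribution up to 25 nonzero pairs, tie-corrected normal approximation beyond),
Bonferroni-corrected. Multi-condition contrasts use the Quade rank test
(blocks = sentences weighted by the rank of their within-block range; F
reference distribution) with Conover pairwise post-hoc comparisons; both are
validated against a within-block permutation oracle rather than tables, and the
all-identical-treatments case returns p = 1 rather than 0/0.

## Synthetic data generator

The generator emulates the *statistical* structure of the study's two data
sources; no phonetic realism is attempted.

* **Reference corpus**: 14 articulatory trajectories per sentence = mixed
  band-limited Gaussian noise, gated by a speech envelope (raised-cosine ramps,
  250 ms silent margins) and confined to a 0.5–5 Hz "speech-movement band"
  (articulators carry syllable- and phone-rate energy; within-sentence drift
  below 0.5 Hz is negligible). The mel track is a fixed smooth map of the EMA
  track: a well-conditioned affine core in (EMA, overall articulatory effort)
  plus a small tanh component — speech spectral envelopes live close to a
  low-dimensional articulatory manifold, and the map must remain dominantly
  linear for the study's premise (linear decodability) to hold. F0 is a
  two-state semi-Markov voiced/unvoiced process (minimum state duration 100 ms,
  so the 50 ms misdetection filters have work to do) with a smooth contour in
  [80, 300] Hz. Audio is synthesized by the vocoder back end.
* **Patient corpus**: the same sentences resampled along random strictly
  monotone warps (strength-controlled, endpoints fixed), an affine per-corpus
  speaker shift on the mel features and a pitch scale on F0 ("different speakers
  of different genders").
* **Neural signals**: each electrode carries a lagged linear drive over the
  patient's latent speech features. Frontal electrodes read orthonormal
  combinations of the articulatory coordinates; temporal electrodes read mel/F0
  combinations chosen (minimum-norm) so that the whole montage spans the latent
  space with orthonormal effective directions, the montage sum pointing along
  the F0 direction so that median referencing cannot delete a mel-relevant
  direction; F0 — step-like, not band-limited — is carried by one dedicated
  electrode. The drive is encoded as shallow amplitude modulation of a shared
  per-band carrier comb (band power is then linear in the drive) plus an
  additive low-frequency copy (read directly by the 0.5–5 Hz feature), a small
  broadband floor (so z-scored band features keep genuine variance), a shared
  50 Hz line artifact (removed exactly by the median reference), and 1/f noise
  scaled by `noise_sd`.

Identical seeds reproduce corpora bit-exactly. The default `noise_sd` is
calibrated so that realistic direct-decoding medians land near 0.4–0.6 — a
convenience anchor to the regime reported for real ECoG, not a claim about SNR.

**What passing tests show** — that every pipeline stage is implemented to its
contract and that the chain recovers known ground truth (warps, articulatory
trajectories, spectral features) under controlled conditions. **What they do not
show** — anything about decodability of real cortical activity: the synthetic
readout is linear by construction, the articulatory-acoustic map is nearly
affine, and the noise is stationary; real ECoG offers none of these guarantees.

## Noise-free recovery conditions

The parameter-recovery experiments (all five decoders on a noise-free 40-sentence,
16-electrode corpus) use features computed **without** median referencing: with
`noise_sd = 0` the only shared artifact is the constant-amplitude line tone,
which z-scoring neutralizes, while a median over 16 statistically independent
channels would inject order-statistic noise (on a 72-electrode montage this cost
shrinks roughly with 1/n). Realistic (noisy) experiments always apply the
reference. Recovery correlations are reported per feature as the median over
held-out sentences of the per-sentence Pearson r.

## Problem sizes

The shipped experiments are scaled to a single CPU: corpora of 12–40 sentences of
2.4–3.4 s at 16 electrodes (1 kHz), synthesizer networks of 2×128 units without
dropout for the test suite (the 3×512 default is exercised architecturally), PLS
with up to 40 components, Quade calibration with 2,000 null simulations and a
100,000-permutation oracle. These sizes are stated here as the package's own
defaults for its synthetic studies.

## Known limitations

* The vocoder is magnitude-only (zero-phase filtering of the excitation); no
  aperiodicity/mixed excitation, so breathy or transient sounds are not modelled.
* The F0 tracker is a plain autocorrelation estimator; at F0 near the frame rate
  of the analysis hop (~100 Hz) the window-period beat degrades voicing decisions.
* The L-curve corner on nearly noise-free problems is ill-defined; the documented
  fallback (smallest strength) makes the choice deterministic.
* DTW is run per sentence pair, anchored at both ends; long silences at sentence
  edges can absorb path slack.
* The Quade test's F approximation is used for inference; the permutation oracle
  exists for validation, not for routine use.
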