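# ecogspeech

Continuous decoding of overt speech from electrocorticographic (ECoG)
activity with linear methods — the complete offline study pipeline,
reimplemented as a tested Python library and driven by a synthetic
paired-corpus generator with known ground truth.

Speech brain-computer interfaces that reconstruct speech frame by frame need
decoders fast enough for millisecond-scale closed loops. Linear decoders
qualify, but they have rarely been compared head-to-head for continuous
speech reconstruction from intracranial activity. This package implements
that comparison end to end:

* a **vocoder** front/back end: order-24 mel-cepstral analysis
  (all-pass warping constant α = 0.455 for 22,050 Hz audio, 220-sample frame
  shift, resampled to 100 Hz) plus F0 in [80, 300] Hz, and synthesis driven
  by an impulse-train/noise excitation at the reconstructed pitch period
  `fs/F0`;
* **neural features**: common median referencing, 21 features per electrode
  (10 Hz band powers from 0–200 Hz over 200 ms Hamming windows + the
  0.5–5 Hz component), frontal/temporal electrode subsets, and
  context/delay windowing of the feature stream `x(t)` against targets
  `y(t + τ)`;
* **articulatory transfer**: the patient's unrecorded articulatory
  trajectories are estimated by DTW-aligning a reference speaker's
  utterances of the same sentences (27-dimensional acoustic feature
  distance, sum-of-squares sample cost) and dragging the reference
  14-channel midsagittal EMA through the warp;
* **five linear decoders** sharing one preprocessing pipeline
  (z-score → delay → PCA → context): OLS, ridge with the L-curve corner,
  ridge with cross-validated λ, ridge with per-output λ, and PLS2 (reduction
  after context concatenation);
* an **articulatory-to-acoustic network** (12 EMA frames → 25 mel
  coefficients; 3×512 tanh units, 25% dropout, Adam, early stopping) used
  for the indirect decoding paradigm, with fine-tuning on decoded
  trajectories;
* the **evaluation framework**: sentence-level 10-fold cross-validation,
  per-sentence Pearson/MSE, frame-shuffled chance levels,
  Bonferroni-corrected Wilcoxon signed-rank contrasts, and the
  Quade–Conover blocked comparison.

The real patient recordings cannot be redistributed, so the `syndata` module
generates paired reference/patient corpora — warped, speaker-shifted
re-utterances with multichannel neural signals derived from a known lagged
readout of the speech latents — making every stage testable against ground
truth. See `docs/methods.md` for the models, parameter choices and their
rationale.

## Worked example

`examples/04_articulatory_transfer.py` runs the cross-speaker transfer on a
small synthetic corpus with known warps:

```
$ python examples/04_articulatory_transfer.py
s000: warp error 0.26 frames (3 ms), transferred-EMA r: min 0.996, median 0.999
s001: warp error 0.24 frames (2 ms), transferred-EMA r: min 0.998, median 0.999
s002: warp error 0.25 frames (3 ms), transferred-EMA r: min 0.998, median 0.999
s003: warp error 0.31 frames (3 ms), transferred-EMA r: min 0.985, median 0.998
errors of ~1-2 frames and r > 0.95 mean the DTW transfer recovers the
patient's articulation to within the frame rate
```

The warp error is the mean absolute difference (in 10 ms frames) between the
estimated and true time alignment; `r` correlates the transferred
articulatory trajectories with the generator's ground truth, per feature.
The other scripts in `examples/` walk through the vocoder roundtrip, corpus
generation, neural feature extraction, the five-decoder comparison, and the
full cross-validated evaluation with chance levels and statistics.

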