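"""Neural feature extraction: referencing, band power, region selection.

Takes one synthetic patient sentence, applies common median referencing,
extracts the 21 features per electrode (20 band-power features in 10 Hz
bands from 0 to 200 Hz plus the 0.5-5 Hz component), and shows the
frontal/temporal split and the context/delay windowing used for decoding.
"""

import numpy as np

from ecogspeech import neurofeat, syndata

cfg = syndata.SynthConfig(n_sentences=1, n_electrodes=8, seed=2,
                          with_audio=False)
_, _, pat, _ = syndata.make_paired_corpora(cfg)
rec = pat[0].neural_raw
print(f"raw recording: {rec.n_channels} channels x {rec.n_samples} samples "
      f"at {rec.rate:.0f} Hz")

ref = neurofeat.common_median_reference(rec)
print(f"median across channels after referencing: "
      f"{np.abs(np.median(ref.data, axis=0)).max():.2e} (exactly zero)")

feat = neurofeat.spectral_features(ref)
per_channel = neurofeat.FEATURES_PER_CHANNEL
print(f"features: {feat.n_frames} frames x {feat.n_features} "
      f"({rec.n_channels} channels x {per_channel} features/channel)")
print(f"a 72-electrode montage would give {72 * per_channel} features per frame")

frontal = neurofeat.select_region(feat, ref.montage, "frontal")
temporal = neurofeat.select_region(feat, ref.montage, "temporal")
print(f"frontal subset: {frontal.n_features} features; "
      f"temporal subset: {temporal.n_features}")

windowed = neurofeat.window_features(
    feat, neurofeat.WindowingConfig(context_ms=210.0, delay_ms=0.0)
)
print(f"with 210 ms context (21 frames) the decoder input is "
      f"{windowed.n_features} wide")
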