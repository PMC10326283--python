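"""Generate paired reference/patient corpora with known ground truth.

The reference corpus mimics an articulatory-acoustic recording session
(14 EMA trajectories + vocoder features + audio per sentence); the patient
corpus re-utters the same sentences with warped timing, a speaker shift on
the mel features, and multichannel neural signals generated from a known
readout of the speech latents.  Prints the corpus structure and writes one
sentence's tracks as tab-separated tables.
"""

import tempfile
from pathlib import Path

import numpy as np

from ecogspeech import syndata
from ecogspeech.tracks import write_manifest

cfg = syndata.SynthConfig(n_sentences=4, n_electrodes=8, warp_strength=0.3,
                          speaker_shift=1.0, noise_sd=1.0, seed=0)
ref, ref_gt, pat, pat_gt = syndata.make_paired_corpora(cfg)

print(f"{len(ref)} sentences per corpus")
s, p = ref[0], pat[0]
print(f"reference '{s.sentence_id}': {s.n_frames} frames, "
      f"EMA {s.tracks['ema'].data.shape}, mel {s.tracks['mel'].data.shape}, "
      f"audio {s.waveform.duration:.2f} s")
print(f"patient   '{p.sentence_id}': {p.n_frames} frames, "
      f"neural {p.neural_raw.n_channels} channels at {p.neural_raw.rate:.0f} Hz")
warp = pat_gt.true_warps[p.sentence_id]
print(f"true warp: maps {len(warp)} patient frames onto reference "
      f"positions [0, {warp[-1]:.0f}], monotone: {bool(np.all(np.diff(warp) > 0))}")
print(f"montage: {dict(pat_gt.montage['region'].value_counts())}")

out = Path(tempfile.mkdtemp(prefix="ecogspeech_"))
s.tracks["ema"].write(out / f"{s.sentence_id}_ema.tsv")
s.tracks["mel"].write(out / f"{s.sentence_id}_mel.tsv")
s.waveform.write(out / f"{s.sentence_id}.wav")
write_manifest(ref, out / "manifest.tsv")
print(f"wrote example tracks to {out}")
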