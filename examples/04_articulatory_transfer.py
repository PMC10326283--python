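"""Cross-speaker articulatory transfer by dynamic time warping.

The patient's articulatory trajectories were never recorded.  This script
aligns each reference utterance onto the patient's re-utterance of the same
sentence with DTW on acoustic features (normalized mel + F0 + speech flag)
and drags the reference EMA through the warp.  Because the corpus is
synthetic, the true warp and the true patient EMA are known, so the script
prints the warp recovery error (frames) and the per-sentence correlation
between transferred and true articulatory trajectories.
"""

import numpy as np

from ecogspeech import artalign, syndata

cfg = syndata.SynthConfig(n_sentences=4, n_electrodes=8, warp_strength=0.3,
                          speaker_shift=0.0, noise_sd=0.0, with_audio=True,
                          seed=21)
ref, _, pat, pat_gt = syndata.make_paired_corpora(cfg)

for r, p in zip(ref, pat):
    est, path = artalign.estimate_patient_ema(r, p)
    m = p.n_frames
    pos = artalign.path_to_ref_positions(path, m) * (r.n_frames - 1) / (m - 1)
    mae = np.mean(np.abs(pos - pat_gt.true_warps[p.sentence_id]))
    rs = [
        np.corrcoef(est.data[:, j], p.tracks["ema"].data[:, j])[0, 1]
        for j in range(est.n_features)
    ]
    print(f"{p.sentence_id}: warp error {mae:.2f} frames "
          f"({mae * 10:.0f} ms), transferred-EMA r: "
          f"min {min(rs):.3f}, median {np.median(rs):.3f}")
print("errors of ~1-2 frames and r > 0.95 mean the DTW transfer recovers "
      "the patient's articulation to within the frame rate")
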