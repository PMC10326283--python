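import numpy as np
import pytest

from ecogspeech import neurofeat, syndata


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpora():
    """Small noise-free paired corpora without audio (fast, deterministic)."""
    cfg = syndata.SynthConfig(
        n_sentences=12, n_electrodes=16, noise_sd=0.0, warp_strength=0.0,
        speaker_shift=0.0, with_audio=False, seed=11,
    )
    ref, ref_gt, pat, pat_gt = syndata.make_paired_corpora(cfg)
    return cfg, ref, ref_gt, pat, pat_gt


@pytest.fixture(scope="session")
def audio_corpora():
    """Small paired corpora with synthesized audio and warped timing."""
    cfg = syndata.SynthConfig(
        n_sentences=6, n_electrodes=8, noise_sd=0.0, warp_strength=0.3,
        speaker_shift=0.0, with_audio=True, seed=21,
    )
    ref, ref_gt, pat, pat_gt = syndata.make_paired_corpora(cfg)
    return cfg, ref, ref_gt, pat, pat_gt


@pytest.fixture(scope="session")
def featured_patients(small_corpora):
    """Patient sentences with neural feature tracks attached.

    The corpus is noise-free, so features are computed without median
    referencing (there is no stochastic artifact for it to remove, and on a
    small montage the reference would only inject order-statistic noise).
    """
    _, _, _, pat, _ = small_corpora
    return neurofeat.attach_features(pat, reference=False)
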