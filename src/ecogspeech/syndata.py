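"""Synthetic paired reference/patient corpora with known ground truth.

The real study combines two datasets that cannot be redistributed: a
reference speaker's articulatory-acoustic corpus (synchronized 14-channel
EMA + audio) and a patient's ECoG recordings of the same sentences.  This
module emulates their statistical structure so that every pipeline stage
has a testable ground truth:

* a *reference* corpus: smooth band-limited (~8 Hz) articulatory
  trajectories, a fixed smooth nonlinear articulatory-to-acoustic map
  producing the 25-coefficient mel cepstrum, a semi-Markov voiced/unvoiced
  F0 contour in [80, 300] Hz, and audio synthesized by the vocoder back end;
* a *patient* corpus: the same sentences re-uttered along a random strictly
  monotone time warp, with an affine per-corpus speaker shift on the mel
  features (different speaker, different gender) and a pitch scale on F0;
* multichannel neural signals generated as lagged readouts of the patient's
  latent speech features: each electrode amplitude-modulates a narrow-band
  carrier (band power then tracks a linear mixture of the latents) on top
  of 1/f background noise.  Electrodes driven by articulatory latents are
  tagged "frontal", those driven by acoustic latents "temporal", giving the
  frontal/temporal analysis a known ground truth.

Identical seeds reproduce corpora bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, sosfiltfilt

from . import acoustics
from .tracks import FRAME_RATE, FeatureTrack, NeuralRecording, SentenceRecord

EMA_CUTOFF_HZ = 8.0
_DEPTH = 0.25   # carrier amplitude-modulation depth
_ADD = 0.6     # weight of the additive low-frequency drive copy
_FLOOR = 0.01  # broadband recording floor relative to signal power
_TILT = 2.0
_CARRIERS = 35.0 + 10.0 * np.arange(16)
N_MEL = 25
SILENCE_C0 = -4.0


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic corpora.

    ``noise_sd`` scales 1/f background noise relative to each electrode's
    deterministic signal power; ``warp_strength`` in [0, 1) controls how far
    the patient's timing deviates from the reference (0 = identical timing);
    ``speaker_shift`` scales the affine mel shift between speakers
    (0 = same speaker).
    """

    n_sentences: int = 20
    duration_range: tuple[float, float] = (2.4, 3.4)
    n_electrodes: int = 16
    n_latent: int = 14
    readout_lags_ms: tuple[float, ...] = (0.0, 20.0, 40.0)
    noise_sd: float = 1.5
    warp_strength: float = 0.3
    speaker_shift: float = 1.0
    neural_rate: float = 1000.0
    with_audio: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_sentences < 1:
            raise ValueError("need at least one sentence")
        if self.duration_range[0] <= 0 or self.duration_range[1] <= 0:
            raise ValueError("durations must be positive")
        if not (0 <= self.warp_strength < 1):
            raise ValueError("warp_strength must lie in [0, 1)")


@dataclass
class ArticMap:
    """Fixed smooth nonlinear articulatory-to-acoustic map.

    Dominantly affine in the articulatory coordinates plus an overall
    activity level (speech spectral envelopes live close to a
    low-dimensional articulatory manifold), with a small smooth tanh
    component providing the genuinely nonlinear part.
    """

    lin: np.ndarray  # (n_latent + 1) x 25, last row couples the activity
    b2: np.ndarray
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    nonlin_scale: float = 0.12

    def __call__(self, ema: np.ndarray) -> np.ndarray:
        # smooth rectifier: overall articulatory effort, differentiable so
        # gradient-trained synthesizers can represent it
        activity = np.mean(np.sqrt(ema**2 + 0.09), axis=1, keepdims=True) - 0.3
        v = np.concatenate([ema, activity], axis=1)
        h = np.tanh(ema @ self.w1 + self.b1)
        return self.b2 + v @ self.lin + self.nonlin_scale * (h @ self.w2)


@dataclass
class GroundTruth:
    artic_map: ArticMap | None = None
    true_warps: dict[str, np.ndarray] = field(default_factory=dict)
    readout_matrix: np.ndarray | None = None  # electrodes x latents
    readout_lags_ms: np.ndarray | None = None
    carrier_hz: np.ndarray | None = None
    montage: pd.DataFrame | None = None
    mel_shift_scale: np.ndarray | None = None
    mel_shift_offset: np.ndarray | None = None
    f0_scale: float = 1.0
    latent_scale: dict = field(default_factory=dict)


def _smooth_noise(rng: np.random.Generator, n: int, n_cols: int,
                  cutoff: float = EMA_CUTOFF_HZ, tilt_hz: float | None = None) -> np.ndarray:
    """Unit-variance smooth Gaussian noise columns, band-limited at ~8 Hz.

    A first-order tilt (pole ~2 Hz) concentrates power at the slow
    movement rates of real articulator trajectories before the low-pass
    cutoff is applied.
    """
    if tilt_hz is None:
        tilt_hz = _TILT
    sos = butter(4, cutoff, fs=FRAME_RATE, output="sos")
    pad = 200
    x = rng.standard_normal((n + 2 * pad, n_cols))
    if tilt_hz is not None:
        sos_tilt = butter(1, tilt_hz, fs=FRAME_RATE, output="sos")
        x = sosfiltfilt(sos_tilt, x, axis=0)
    x = sosfiltfilt(sos, x, axis=0)[pad : pad + n]
    return x / x.std(axis=0, keepdims=True)




def _movement_band(x: np.ndarray) -> np.ndarray:
    """Confine trajectories to the 0.5-5 Hz speech-movement band.

    Within a sentence, articulator trajectories carry syllable- and
    phone-rate energy; posture drift below ~0.5 Hz is negligible.  Applied
    after envelope gating so the silent margins stay (close to) still.
    """
    sos = butter(4, (0.5, 5.0), btype="bandpass", fs=FRAME_RATE, output="sos")
    pad = 400
    xp = np.pad(x, ((pad, pad), (0, 0)), mode="reflect")
    y = sosfiltfilt(sos, xp, axis=0)[pad : pad + len(x)]
    sd = y.std(axis=0, keepdims=True)
    return y / np.maximum(sd, 1e-12)

def _envelope(n: int) -> np.ndarray:
    """Speech-activity envelope: silent margins with raised-cosine ramps."""
    t = np.arange(n) / FRAME_RATE
    dur = n / FRAME_RATE
    sil, ramp = 0.25, 0.15
    up = np.clip((t - sil) / ramp, 0, 1)
    down = np.clip((dur - sil - t) / ramp, 0, 1)
    return 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))


def _voicing_f0(rng: np.random.Generator, env: np.ndarray) -> np.ndarray:
    """Semi-Markov voiced/unvoiced F0 contour inside the speech envelope.

    Minimum state duration 100 ms, so the downstream 50 ms misdetection
    filters have genuine short-run structure to preserve or remove.
    """
    n = len(env)
    min_dur = int(0.100 * FRAME_RATE)
    voiced = np.zeros(n, dtype=bool)
    state = rng.random() < 0.6
    i = 0
    while i < n:
        dur = min_dur + rng.geometric(0.06)
        voiced[i : i + dur] = state
        state = not state
        i += dur
    voiced &= env > 0.5
    base = 150.0 + 25.0 * _smooth_noise(rng, n, 1, cutoff=2.0)[:, 0]
    f0 = np.where(voiced, np.clip(base, 80.0, 300.0), 0.0)
    return f0


def make_reference_corpus(config: SynthConfig) -> tuple[list[SentenceRecord], GroundTruth]:
    """Reference-speaker corpus: EMA + mel + F0 (+ audio) per sentence."""
    rng = np.random.default_rng(config.seed)
    n_hidden = 20
    # well-conditioned affine core: singular values within [0.8, 1.2]
    d = config.n_latent + 1
    u_, _ = np.linalg.qr(rng.standard_normal((N_MEL, d)))
    v_, _ = np.linalg.qr(rng.standard_normal((d, d)))
    lin = (u_ * rng.uniform(0.8, 1.2, d)) @ v_.T
    lin = lin.T  # d x 25
    lin[:-1, 0] *= 0.1
    lin[-1, :] *= 0.3
    lin[-1, 0] = 3.2  # the energy coefficient tracks articulatory activity
    artic_map = ArticMap(
        lin=lin,
        b2=np.concatenate([[SILENCE_C0], 0.2 * rng.standard_normal(N_MEL - 1)]),
        w1=0.4 * rng.standard_normal((config.n_latent, n_hidden)) / np.sqrt(config.n_latent),
        b1=0.15 * rng.standard_normal(n_hidden),
        w2=rng.standard_normal((n_hidden, N_MEL)) / np.sqrt(n_hidden),
    )
    mix = rng.standard_normal((config.n_latent, config.n_latent))
    mix /= np.linalg.norm(mix, axis=0, keepdims=True)

    sentences = []
    for s in range(config.n_sentences):
        dur = rng.uniform(*config.duration_range)
        n = int(round(dur * FRAME_RATE))
        env = _envelope(n)
        ema = (_smooth_noise(rng, n, config.n_latent) @ mix) * env[:, None]
        ema = _movement_band(ema)
        mel = artic_map(ema)
        f0 = _voicing_f0(rng, env)

        ema_t = FeatureTrack(ema, [f"ema_{j}" for j in range(config.n_latent)])
        mel_t = FeatureTrack(mel, list(acoustics.MEL_LABELS))
        f0_t = FeatureTrack(f0[:, None], ["f0"])
        wav = None
        if config.with_audio:
            wav = acoustics.mlsa_synthesize(mel_t, f0_t, seed=int(config.seed * 7919 + s))
        sentences.append(
            SentenceRecord(
                sentence_id=f"s{s:03d}",
                text=f"synthetic sentence {s}",
                condition="read" if s % 2 == 0 else "repeat",
                speaker="ref",
                waveform=wav,
                tracks={"ema": ema_t, "mel": mel_t, "f0": f0_t},
            )
        )
    return sentences, GroundTruth(artic_map=artic_map)


def _random_warp(rng: np.random.Generator, n: int, m: int, strength: float) -> np.ndarray:
    """Strictly increasing map from patient frames [0, m) to reference
    positions [0, n-1], endpoints fixed."""
    if strength == 0:
        return np.linspace(0.0, n - 1.0, m)
    wig = _smooth_noise(rng, m, 1, cutoff=1.5)[:, 0]
    rate = np.exp(strength * 1.2 * wig)
    pos = np.concatenate([[0.0], np.cumsum(rate)[:-1]])
    return pos / pos[-1] * (n - 1.0)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-shaped noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def default_montage(n_electrodes: int) -> pd.DataFrame:
    """Half the electrodes over articulatory (frontal) cortex, half over
    auditory (temporal) cortex."""
    n_frontal = n_electrodes // 2
    return pd.DataFrame(
        {
            "channel_id": [f"e{i:02d}" for i in range(n_electrodes)],
            "region": ["frontal"] * n_frontal + ["temporal"] * (n_electrodes - n_frontal),
        }
    )


def make_patient_corpus(
    ref_corpus: list[SentenceRecord], config: SynthConfig
) -> tuple[list[SentenceRecord], GroundTruth]:
    """Patient corpus: warped, speaker-shifted re-utterances + ECoG signals.

    Each patient sentence is the reference sentence's tracks resampled
    along a random strictly monotone warp; mel features get a fixed
    per-corpus affine speaker shift and F0 a pitch scale.  Raw neural
    signals encode lagged linear drives derived from the patient's latent
    speech features: frontal electrodes read orthonormal combinations of
    the articulatory coordinates, temporal electrodes read mel/F0
    combinations chosen (minimum-norm) so that the full electrode set spans
    the latent space with orthonormal effective directions — i.e. the
    recording carries a well-conditioned, linearly invertible image of the
    speech features, as a usable ECoG montage would.
    """
    if not ref_corpus:
        raise ValueError("empty reference corpus")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    n_lat_ema = ref_corpus[0].tracks["ema"].n_features

    montage = default_montage(config.n_electrodes)
    frontal = (montage["region"] == "frontal").to_numpy()
    lags = np.array(
        [config.readout_lags_ms[e % len(config.readout_lags_ms)]
         for e in range(config.n_electrodes)]
    )

    shift_scale = 1.0 + config.speaker_shift * 0.12 * rng.standard_normal(N_MEL)
    shift_offset = config.speaker_shift * 0.45 * rng.standard_normal(N_MEL)
    shift_offset[0] = config.speaker_shift * 0.2 * rng.standard_normal()
    shift_scale[0] = 1.0  # keep the energy coefficient on the same scale
    f0_scale = 1.0 + config.speaker_shift * 0.25

    # ---- pass 1: warped, speaker-shifted patient feature tracks ----------
    warps: dict[str, np.ndarray] = {}
    ema_list, mel_list, f0_list = [], [], []
    for ref in ref_corpus:
        n = ref.n_frames
        if config.warp_strength > 0:
            m = max(2, int(round(n * (1.0 + 0.15 * config.warp_strength
                                      * rng.uniform(-1, 1)))))
        else:
            m = n
        warp = _random_warp(rng, n, m, config.warp_strength)
        warps[ref.sentence_id] = warp
        grid = np.arange(n, dtype=float)
        ema_p = PchipInterpolator(grid, ref.tracks["ema"].data, axis=0)(warp)
        mel_p = PchipInterpolator(grid, ref.tracks["mel"].data, axis=0)(warp)
        mel_p = mel_p * shift_scale + shift_offset
        f0_ref = ref.tracks["f0"].data[:, 0]
        f0_p = f0_ref[np.clip(np.round(warp).astype(int), 0, n - 1)]
        f0_p = np.where(f0_p > 0, np.clip(f0_p * f0_scale, 80.0, 300.0), 0.0)
        ema_list.append(ema_p)
        mel_list.append(mel_p)
        f0_list.append(f0_p)

    # ---- corpus-level latent statistics ----------------------------------
    ema_all = np.vstack(ema_list)
    mel_all = np.vstack(mel_list)
    f0_all = np.concatenate(f0_list)
    ema_sd = np.maximum(ema_all.std(0), 1e-6)
    act_all = np.mean(np.abs(ema_all), axis=1)
    act_m, act_sd = act_all.mean(), max(act_all.std(), 1e-6)
    mel_m, mel_sd = mel_all.mean(0), np.maximum(mel_all.std(0), 1e-6)
    f0_m, f0_sd = f0_all.mean(), max(f0_all.std(), 1e-6)

    def latent_z(ema_p, mel_p, f0_p):
        """40-dim readout basis: normalized EMA, z-scored mel, z-scored F0."""
        return np.column_stack([
            ema_p / ema_sd,
            (mel_p - mel_m) / mel_sd,
            (f0_p - f0_m) / f0_sd,
        ])

    # ---- electrode readout: orthonormal effective latent directions ------
    k = n_lat_ema + 2  # normalized EMA coords + activity + F0
    zeta = np.column_stack([
        ema_all / ema_sd,
        (act_all - act_m) / act_sd,
        ((f0_all - f0_m) / f0_sd),
    ])
    acou = np.column_stack([(mel_all - mel_m) / mel_sd,
                            (f0_all - f0_m) / f0_sd])
    n_front = int(frontal.sum())
    q = np.linalg.qr(rng.standard_normal((n_lat_ema, n_lat_ema)))[0]
    front_rows = [q[:, i % n_lat_ema] for i in range(n_front)]
    front_ext = np.stack(
        [np.concatenate([r, np.zeros(2)]) for r in front_rows]
    ) if n_front else np.zeros((0, k))
    n_temp = config.n_electrodes - n_front
    # one dedicated temporal electrode carries the (step-like) F0 drive so
    # its broadband temporal structure cannot contaminate the smooth
    # articulatory/acoustic directions carried by the other electrodes
    f0_row = np.zeros(k)
    f0_row[-1] = 1.0
    g = rng.standard_normal((k, max(n_temp, 1)))
    g[-1, :] = 0.0  # remaining rows span the smooth (EMA/activity) subspace
    if len(front_ext):
        g -= front_ext.T @ (front_ext @ g)
    smooth_targets = np.linalg.qr(g)[0][:, : max(n_temp - 1, 0)].T
    if len(smooth_targets):
        # balance the montage: the electrode rows sum to the (pure) F0
        # direction, so common-mode referencing — which subtracts roughly
        # the mean drive — cannot delete any articulatory/acoustic latent
        # direction from the recording's span
        excess = front_ext.sum(axis=0) + smooth_targets.sum(axis=0)
        smooth_targets = smooth_targets - excess / len(smooth_targets)
    temp_targets = np.vstack([smooth_targets, f0_row[None, :]])[:n_temp]

    readout = np.zeros((config.n_electrodes, n_lat_ema + N_MEL + 1))
    fi = ti = 0
    for e in range(config.n_electrodes):
        if frontal[e]:
            readout[e, :n_lat_ema] = front_rows[fi]
            fi += 1
        else:
            target = zeta @ temp_targets[ti]
            w, *_ = np.linalg.lstsq(acou, target - target.mean(), rcond=None)
            readout[e, n_lat_ema:] = w
            ti += 1

    gt = GroundTruth(
        readout_matrix=readout,
        readout_lags_ms=lags,
        carrier_hz=_CARRIERS.copy(),
        montage=montage,
        mel_shift_scale=shift_scale,
        mel_shift_offset=shift_offset,
        f0_scale=f0_scale,
        true_warps=warps,
        latent_scale={"ema_sd": ema_sd, "mel_mean": mel_m, "mel_sd": mel_sd,
                      "f0_mean": f0_m, "f0_sd": f0_sd},
    )

    # ---- pass 2: neural synthesis + record assembly ----------------------
    patients = []
    for s_idx, ref in enumerate(ref_corpus):
        ema_p, mel_p, f0_p = ema_list[s_idx], mel_list[s_idx], f0_list[s_idx]
        z = latent_z(ema_p, mel_p, f0_p)
        neural = _synthesize_neural(z, config, gt, rng, len(ema_p))
        mel_t = FeatureTrack(mel_p, list(acoustics.MEL_LABELS))
        f0_t = FeatureTrack(f0_p[:, None], ["f0"])
        wav = None
        if config.with_audio:
            wav = acoustics.mlsa_synthesize(
                mel_t, f0_t, seed=int(config.seed * 104729 + s_idx)
            )
        patients.append(
            SentenceRecord(
                sentence_id=ref.sentence_id,
                text=ref.text,
                condition=ref.condition,
                speaker="patient",
                waveform=wav,
                tracks={
                    "ema": FeatureTrack(ema_p, list(ref.tracks["ema"].labels)),
                    "mel": mel_t,
                    "f0": f0_t,
                },
                neural_raw=neural,
            )
        )
    return patients, gt


def _synthesize_neural(
    z: np.ndarray, config: SynthConfig, gt: GroundTruth,
    rng: np.random.Generator, n_frames: int,
) -> NeuralRecording:
    """Raw electrode signals from latent features (see module docstring)."""
    fs = config.neural_rate
    n_samples = int(round(n_frames / FRAME_RATE * fs))
    t = np.arange(n_samples) / fs
    t_frames = np.arange(n_frames) / FRAME_RATE
    u_all = z @ gt.readout_matrix.T  # frames x electrodes

    # one carrier comb (a carrier per 10 Hz band), shared by all
    # electrodes with identical phases: under the common-median reference
    # the median then acts as a shared amplitude reference and the
    # referenced band power stays (nearly) linear in the latent drives
    carrier_wave = np.sin(
        2 * np.pi * np.outer(_CARRIERS, t)
        + rng.uniform(0, 2 * np.pi, (len(_CARRIERS), 1))
    ).sum(axis=0) / np.sqrt(len(_CARRIERS))
    data = np.empty((config.n_electrodes, n_samples))
    for e in range(config.n_electrodes):
        lag_s = gt.readout_lags_ms[e] / 1000.0
        u = np.interp(t - lag_s, t_frames, u_all[:, e])
        # shallow broadband amplitude modulation: the squared smoothed
        # amplitude (band power) stays essentially linear in the latent
        # drive, and every spectral band carries an informative carrier
        amp = np.sqrt(np.clip(1.0 + _DEPTH * u, 0.02, None))
        det = amp * carrier_wave + _ADD * u
        # broadband recording floor: band-power estimates keep genuine
        # variance so z-scored features are well-behaved
        floor = _FLOOR * det.std() * rng.standard_normal(n_samples)
        noise = _pink_noise(rng, n_samples) * config.noise_sd * det.std()
        data[e] = det + floor + noise
    # shared 50 Hz line-noise artifact: identical on every channel, so the
    # common-median reference removes it exactly
    line = 2.0 * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    data += line
    return NeuralRecording(data, fs, gt.montage.copy())


def apply_artic_map(gt: GroundTruth, ema: FeatureTrack) -> FeatureTrack:
    """Regenerate the mel track from EMA via the stored ground-truth map."""
    if gt.artic_map is None:
        raise ValueError("ground truth carries no articulatory map")
    return FeatureTrack(gt.artic_map(ema.data), list(acoustics.MEL_LABELS))


def make_paired_corpora(config: SynthConfig):
    """Convenience wrapper: reference corpus, patient corpus, ground truths."""
    ref, ref_gt = make_reference_corpus(config)
    pat, pat_gt = make_patient_corpus(ref, config)
    return ref, ref_gt, pat, pat_gt
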