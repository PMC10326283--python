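"""Neural signal referencing, spectral features, and context/delay windowing.

Per electrode, 21 features are computed on the shared 100 Hz frame grid:
20 band-averaged power-spectral-density features (10 Hz bands from 0 to
200 Hz, short-time periodogram over a 200 ms Hamming window with a 10 ms
shift) plus the raw signal band-passed between 0.5 and 5 Hz.  A 72-electrode
montage therefore yields 1,512 features per frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, get_window, sosfiltfilt

from .tracks import FRAME_RATE, FeatureTrack, NeuralRecording

N_BANDS = 20
BAND_WIDTH = 10.0  # Hz
LOWFREQ_BAND = (0.5, 5.0)  # Hz
FEATURES_PER_CHANNEL = N_BANDS + 1
WINDOW_MS = 200.0
SHIFT_MS = 10.0

REGIONS = ("frontal", "temporal")


@dataclass(frozen=True)
class WindowingConfig:
    """Temporal context and delay for decoding.

    ``context_ms`` is the total length of the symmetric context window (an
    odd number of 10 ms frames; e.g. 210 ms -> 21 frames, +/-10).
    ``delay_ms`` shifts the centre of the neural window relative to the
    decoded frame: negative values use neural activity from the past.
    """

    context_ms: float = 0.0
    delay_ms: float = 0.0

    @property
    def context_frames(self) -> int:
        k = int(round(self.context_ms / SHIFT_MS))
        return k + 1 if k % 2 == 0 else k

    @property
    def half_context(self) -> int:
        return (self.context_frames - 1) // 2

    @property
    def delay_frames(self) -> int:
        d = self.delay_ms / SHIFT_MS
        if abs(d - round(d)) > 1e-9:
            raise ValueError("delay must be an integer multiple of 10 ms")
        return int(round(d))


def common_median_reference(rec: NeuralRecording) -> NeuralRecording:
    """Subtract the across-channel median at every sample.

    Removes shared artifacts (line noise, electromagnetic interference) and
    is more outlier-robust than an average reference.  Idempotent: once the
    per-sample median is zero, a second pass changes nothing.
    """
    if rec.n_channels < 2:
        raise ValueError("common median reference needs at least 2 channels")
    med = np.median(rec.data, axis=0, keepdims=True)
    return NeuralRecording(rec.data - med, rec.rate, rec.montage.copy())


def _frame_centers_samples(n_samples: int, rate: float) -> np.ndarray:
    n_frames = int(round(n_samples / rate * FRAME_RATE))
    return np.round(np.arange(n_frames) / FRAME_RATE * rate).astype(int)


def spectral_features(rec: NeuralRecording) -> FeatureTrack:
    """Per-channel band-power features plus the 0.5-5 Hz component.

    Output columns are ordered channel-major: for each channel, bands
    ``0-10 ... 190-200`` then ``lowfreq``.  Frame ``k`` is centred at
    ``k/100`` s; edges are handled by symmetric signal padding.
    """
    if rec.rate < 2 * N_BANDS * BAND_WIDTH:
        raise ValueError("sampling rate must be at least 400 Hz")
    win_len = int(round(WINDOW_MS / 1000.0 * rec.rate))
    if rec.n_samples < win_len:
        raise ValueError("recording shorter than one analysis window")
    centers = _frame_centers_samples(rec.n_samples, rec.rate)
    n_frames = len(centers)
    window = get_window("hamming", win_len, fftbins=False)
    half = win_len // 2

    freqs = np.fft.rfftfreq(win_len, d=1.0 / rec.rate)
    # periodogram scaling: sum(PSD * df) ~ windowed signal variance
    scale = 1.0 / (rec.rate * np.sum(window**2))
    band_of_bin = np.floor(freqs / BAND_WIDTH).astype(int)
    in_range = band_of_bin < N_BANDS
    # averaging matrix: bands x bins
    band_avg = np.zeros((N_BANDS, len(freqs)))
    for b in range(N_BANDS):
        sel = in_range & (band_of_bin == b)
        band_avg[b, sel] = 1.0 / max(sel.sum(), 1)

    sos = butter(4, LOWFREQ_BAND, btype="bandpass", fs=rec.rate, output="sos")

    out = np.empty((n_frames, rec.n_channels * FEATURES_PER_CHANNEL))
    labels: list[str] = []
    for ch in range(rec.n_channels):
        ch_id = str(rec.montage.iloc[ch]["channel_id"])
        x = rec.data[ch]
        pad = np.pad(x, half, mode="reflect")
        frames = np.stack([pad[c : c + win_len] for c in centers])
        spec = np.fft.rfft(frames * window, axis=1)
        psd = (np.abs(spec) ** 2) * scale
        # one-sided correction (all interior bins carry doubled power)
        psd[:, 1:] *= 2.0
        if win_len % 2 == 0:
            psd[:, -1] /= 2.0
        bands = psd @ band_avg.T  # frames x 20

        # generous reflection padding: the 0.5 Hz band edge rings for
        # seconds, longer than a short sentence, so default transient
        # handling would contaminate the whole output
        lp = int(3 * rec.rate)
        low = sosfiltfilt(sos, np.pad(x, lp, mode="reflect"))[lp : lp + len(x)]
        lowfeat = low[np.clip(centers, 0, len(x) - 1)]

        col = ch * FEATURES_PER_CHANNEL
        out[:, col : col + N_BANDS] = bands
        out[:, col + N_BANDS] = lowfeat
        labels.extend(
            [f"{ch_id}:band{int(b * BAND_WIDTH)}-{int((b + 1) * BAND_WIDTH)}" for b in range(N_BANDS)]
        )
        labels.append(f"{ch_id}:lowfreq")
    return FeatureTrack(out, labels)


def select_region(
    feat: FeatureTrack, montage: pd.DataFrame, region: str
) -> FeatureTrack:
    """Keep only the features of electrodes tagged with ``region``.

    ``region`` is ``"frontal"``, ``"temporal"`` or ``"all"`` (identity).
    """
    if region == "all":
        return feat.copy()
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    keep_ids = set(str(c) for c in montage.loc[montage["region"] == region, "channel_id"])
    cols = [i for i, lab in enumerate(feat.labels) if lab.split(":")[0] in keep_ids]
    if not cols:
        raise ValueError(f"no channels tagged {region!r}")
    return feat.select(cols)


def window_features(feat: FeatureTrack, cfg: WindowingConfig) -> FeatureTrack:
    """Concatenate a symmetric context of frames around ``t + delay``.

    For context ``(2k+1) x 10 ms`` and delay ``tau`` frames, output frame
    ``t`` is the concatenation of input frames ``t+tau-k ... t+tau+k``
    (edge replication outside the sentence).  Negative delay therefore
    shifts the neural window into the past relative to the decoded frame.
    """
    k = cfg.half_context
    tau = cfg.delay_frames
    n = feat.n_frames
    if cfg.context_frames > n:
        raise ValueError("context window larger than the sentence")
    if abs(tau) >= n:
        raise ValueError("delay exceeds sentence duration")
    offsets = np.arange(-k, k + 1) + tau
    idx = np.clip(np.arange(n)[:, None] + offsets[None, :], 0, n - 1)
    data = feat.data[idx]  # n x (2k+1) x f
    data = data.reshape(n, -1)
    labels = [
        f"{lab}@{off:+d}" for off in offsets for lab in feat.labels
    ]
    return FeatureTrack(data, labels, feat.rate)


def attach_features(sentences, region: str = "all", reference: bool = True) -> list:
    """Compute the neural feature track for each sentence record.

    Applies common median referencing (``reference=True``, the default for
    recordings that may carry shared artifacts), spectral feature
    extraction and region selection to each record's raw neural recording,
    and attaches the result as ``tracks["neural"]``.  On an artifact-free
    recording the median reference only injects order-statistic noise from
    the finite montage, so artifact-free analyses may disable it.
    """
    out = []
    for s in sentences:
        if s.neural_raw is None:
            raise ValueError(f"sentence {s.sentence_id} has no neural recording")
        rec = common_median_reference(s.neural_raw) if reference else s.neural_raw
        feat = spectral_features(rec)
        feat = select_region(feat, rec.montage, region)
        out.append(s.with_tracks(neural=feat))
    return out


def delay_features(feat: FeatureTrack, delay_frames: int) -> FeatureTrack:
    """Shift features by ``delay_frames`` with edge replication (no context)."""
    n = feat.n_frames
    idx = np.clip(np.arange(n) + delay_frames, 0, n - 1)
    return FeatureTrack(feat.data[idx], list(feat.labels), feat.rate)
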