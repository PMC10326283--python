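"""Audio preprocessing, speech detection, and vocoder analysis-synthesis.

The speech representation is the classic source-filter split used by
mel-cepstral vocoders: a 25-coefficient mel cepstrum describing the spectral
envelope on an all-pass-warped (mel-like) frequency axis, plus a fundamental
frequency (F0) contour that is 0 on unvoiced frames.  Analysis parameters
follow the standard setup for 22,050 Hz speech: Blackman windows of 400
samples, 1,024-point spectra, a 220-sample frame shift (native frame rate
~100.23 Hz, resampled to the shared 100 Hz grid), all-pass constant
``alpha = 0.455``, and a periodogram floor of 1e-4.

Synthesis drives the per-frame warped spectral envelope with an impulse
train at the reconstructed pitch period (voiced) or white noise (unvoiced),
via frequency-domain overlap-add filtering.  This reproduces the
analysis-synthesis contract of an MLSA-filter vocoder (same alpha, frame
period and excitation convention) with a frequency-domain filter back end.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import get_window, hilbert, resample_poly

from .tracks import FRAME_RATE, FeatureTrack, Waveform

AUDIO_RATE = 22_050
ALPHA = 0.455  # all-pass warping constant for 22,050 Hz
MEL_ORDER = 24
FRAME_SHIFT = 220  # samples at 22,050 Hz -> ~100.23 Hz native frame rate
WINDOW_LEN = 400
FFT_LEN = 1024
PERIODOGRAM_EPS = 1e-4
F0_MIN, F0_MAX = 80.0, 300.0
TARGET_RMS_DB = -20.0

MEL_LABELS = [f"c{m}" for m in range(MEL_ORDER + 1)]


# ---------------------------------------------------------------------------
# preprocessing

def peak_normalize(x: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("cannot peak-normalize an all-zero signal")
    return x / peak


def apply_gain_control(x: np.ndarray, target_db: float = TARGET_RMS_DB) -> np.ndarray:
    """Scale the signal so its RMS level is ``target_db`` dBFS."""
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise ValueError("cannot set loudness of an all-zero signal")
    return x * (10.0 ** (target_db / 20.0) / rms)


def preprocess_audio(w: Waveform) -> Waveform:
    """DC removal, peak normalization, -20 dBFS loudness, resample to 22,050 Hz."""
    x = w.samples - np.mean(w.samples)
    if np.max(np.abs(x)) == 0:
        raise ValueError("cannot preprocess an all-zero signal")
    x = apply_gain_control(peak_normalize(x))
    if w.rate != AUDIO_RATE:
        # polyphase resampling with the built-in anti-aliasing low-pass
        from fractions import Fraction

        frac = Fraction(AUDIO_RATE, int(round(w.rate))).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator)
    return Waveform(x, AUDIO_RATE)


# ---------------------------------------------------------------------------
# speech detection

def detect_speech(w: Waveform) -> list[tuple[float, float]]:
    """Envelope-based voice activity detection.

    Hilbert magnitude envelope -> 100 ms moving average -> threshold at 10%
    of the (per-sentence) maximum -> keep crossings >= 50 ms -> merge
    segments separated by < 100 ms.  Returns (onset, offset) pairs in
    seconds; silent input yields an empty list.
    """
    x = w.samples
    if len(x) == 0 or np.max(np.abs(x)) == 0:
        return []
    env = np.abs(hilbert(x))
    win = max(1, int(round(0.100 * w.rate)))
    smooth = np.convolve(env, np.ones(win) / win, mode="same")
    mask = smooth >= 0.10 * smooth.max()

    # extract runs of True
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    starts, stops = idx[0::2], idx[1::2]
    segs = [
        (s / w.rate, e / w.rate)
        for s, e in zip(starts, stops)
        if (e - s) / w.rate >= 0.050
    ]
    # merge gaps < 100 ms (a merged segment is necessarily >= 50 ms already)
    merged: list[tuple[float, float]] = []
    for seg in segs:
        if merged and seg[0] - merged[-1][1] < 0.100:
            merged[-1] = (merged[-1][0], seg[1])
        else:
            merged.append(seg)
    return merged


def segments_to_flag(
    segments: list[tuple[float, float]], n_frames: int, rate: float = FRAME_RATE
) -> np.ndarray:
    """Sample a segment list onto the frame grid as a 0/1 flag."""
    t = np.arange(n_frames) / rate
    flag = np.zeros(n_frames)
    for on, off in segments:
        flag[(t >= on) & (t < off)] = 1.0
    return flag


def zero_short_runs(x: np.ndarray, min_frames: int) -> np.ndarray:
    """Zero out nonzero runs shorter than ``min_frames`` (misdetection filter)."""
    x = x.copy()
    mask = x != 0
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for s, e in zip(idx[0::2], idx[1::2]):
        if e - s < min_frames:
            x[s:e] = 0
    return x


# ---------------------------------------------------------------------------
# mel-cepstral analysis

def _warp_forward(omega: np.ndarray, alpha: float = ALPHA) -> np.ndarray:
    """Phase response of the all-pass element: linear -> warped frequency."""
    return omega + 2.0 * np.arctan(
        alpha * np.sin(omega) / (1.0 - alpha * np.cos(omega))
    )


def _warp_inverse(theta: np.ndarray, alpha: float = ALPHA) -> np.ndarray:
    """Inverse warp (the all-pass warp with -alpha)."""
    return theta - 2.0 * np.arctan(
        alpha * np.sin(theta) / (1.0 + alpha * np.cos(theta))
    )


def _frame_centers(n_samples: int, hop: int = FRAME_SHIFT) -> np.ndarray:
    n_frames = int(np.floor((n_samples - 1) / hop)) + 1
    return np.arange(n_frames) * hop


def _native_log_spectra(x: np.ndarray) -> np.ndarray:
    """Warped log-amplitude spectra, one row per native (220-hop) frame."""
    centers = _frame_centers(len(x))
    half = WINDOW_LEN // 2
    pad = np.pad(x, half, mode="reflect")
    win = get_window("blackman", WINDOW_LEN, fftbins=False)
    frames = np.stack([pad[c : c + WINDOW_LEN] for c in centers])
    spec = np.fft.rfft(frames * win, FFT_LEN, axis=1)
    power = np.abs(spec) ** 2
    # envelope estimation: fill inter-harmonic valleys by smoothing the
    # periodogram across frequency (width ~ one harmonic spacing), so the
    # cepstrum tracks the spectral envelope rather than the source comb
    k = 9
    kernel = np.ones(k) / k
    power = np.apply_along_axis(
        lambda r: np.convolve(np.pad(r, k // 2, mode="edge"), kernel, mode="valid"),
        1,
        power,
    )
    # Welch-style average over 3 adjacent frames (30 ms): stabilizes the
    # power estimate when the analysis window holds only 1-2 pitch periods
    if len(power) >= 3:
        padded = np.pad(power, ((1, 1), (0, 0)), mode="edge")
        power = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
    power = power + PERIODOGRAM_EPS
    # resample the log power spectrum onto a uniform warped-frequency grid
    n_bins = FFT_LEN // 2 + 1
    omega = np.linspace(0.0, np.pi, n_bins)
    theta = np.linspace(0.0, np.pi, n_bins)
    omega_of_theta = _warp_inverse(theta)
    logp = np.log(power)
    warped = np.stack(
        [np.interp(omega_of_theta, omega, row) for row in logp]
    )
    return 0.5 * warped  # log amplitude


def _cepstrum_from_log_spectrum(log_amp: np.ndarray, order: int = MEL_ORDER) -> np.ndarray:
    """Real cepstrum of a warped log-amplitude spectrum (rows = frames).

    Convention: ``log_amp(theta) ~ c0 + 2 * sum_{m>=1} c_m cos(m theta)``.
    """
    cep = np.fft.irfft(log_amp, axis=-1)
    return cep[..., : order + 1]


def _log_spectrum_from_cepstrum(mc: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate the truncated warped log-amplitude spectrum at angles theta."""
    m = np.arange(1, mc.shape[-1])
    cos = np.cos(np.outer(theta, m))  # n_theta x order
    return mc[..., :1] + 2.0 * mc[..., 1:] @ cos.T


def resample_track_to_100hz(
    values: np.ndarray, native_times: np.ndarray, duration: float, kind: str = "pchip"
) -> np.ndarray:
    """Resample per-frame values onto the t = k/100 s grid.

    ``kind='pchip'`` uses shape-preserving cubic interpolation (continuous
    features); ``kind='nearest'`` preserves discontinuities (F0).
    """
    n_out = int(round(duration * FRAME_RATE))
    t_out = np.arange(n_out) / FRAME_RATE
    values = np.atleast_2d(values.T).T  # frames x features
    if kind == "pchip":
        out = PchipInterpolator(native_times, values, axis=0, extrapolate=True)(t_out)
    elif kind == "nearest":
        idx = np.argmin(np.abs(native_times[None, :] - t_out[:, None]), axis=1)
        out = values[idx]
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")
    return out


def mel_analysis(w: Waveform) -> FeatureTrack:
    """Order-24 mel-cepstral analysis resampled to exactly 100 Hz."""
    if w.rate != AUDIO_RATE:
        raise ValueError("mel_analysis expects 22,050 Hz audio")
    if len(w.samples) < WINDOW_LEN:
        raise ValueError("audio shorter than one analysis window")
    log_amp = _native_log_spectra(w.samples)
    mc = _cepstrum_from_log_spectrum(log_amp)
    centers = _frame_centers(len(w.samples))
    native_t = centers / w.rate
    out = resample_track_to_100hz(mc, native_t, w.duration, kind="pchip")
    return FeatureTrack(out, MEL_LABELS)


# ---------------------------------------------------------------------------
# F0

def extract_f0(w: Waveform, voicing_threshold: float = 0.5) -> FeatureTrack:
    """Autocorrelation F0 estimate constrained to [80, 300] Hz, 0 = unvoiced.

    Framing matches the mel-cepstral analysis (220-sample shift); the track
    is resampled to 100 Hz with nearest-neighbour interpolation and voiced
    runs shorter than 50 ms are zeroed.
    """
    if w.rate != AUDIO_RATE:
        raise ValueError("extract_f0 expects 22,050 Hz audio")
    x = w.samples
    if len(x) < WINDOW_LEN:
        raise ValueError("audio shorter than one analysis window")
    lag_min = int(np.floor(w.rate / F0_MAX))
    lag_max = int(np.ceil(w.rate / F0_MIN))
    seg_len = 4 * lag_max  # a few periods of the lowest admissible F0
    half = seg_len // 2
    pad = np.pad(x, half, mode="reflect")
    centers = _frame_centers(len(x))

    f0 = np.zeros(len(centers))
    global_rms = np.sqrt(np.mean(x**2))
    for i, c in enumerate(centers):
        seg = pad[c : c + seg_len]
        seg = seg - seg.mean()
        # voicing requires energy at the frame centre itself, not just
        # anywhere inside the (long) autocorrelation window: an off-centre
        # burst elsewhere in the window must not mark this frame voiced
        centre = seg[half - FRAME_SHIFT // 2 : half + FRAME_SHIFT // 2]
        centre_rms = np.sqrt(np.mean(centre**2))
        seg_rms = np.sqrt(np.mean(seg**2))
        if centre_rms < 0.05 * global_rms or centre_rms < 0.3 * seg_rms:
            continue
        # normalized autocorrelation via FFT
        n = len(seg)
        f = np.fft.rfft(seg, 2 * n)
        ac = np.fft.irfft(f * np.conj(f))[: lag_max + 2]
        if ac[0] <= 0:
            continue
        ac = ac / ac[0]
        search = ac[lag_min : lag_max + 1]
        k = int(np.argmax(search)) + lag_min
        if ac[k] < voicing_threshold:
            continue
        # parabolic refinement around the peak
        if 1 <= k < len(ac) - 1:
            denom = ac[k - 1] - 2 * ac[k] + ac[k + 1]
            delta = 0.5 * (ac[k - 1] - ac[k + 1]) / denom if denom != 0 else 0.0
            k_ref = k + float(np.clip(delta, -1, 1))
        else:
            k_ref = float(k)
        cand = w.rate / k_ref
        if F0_MIN <= cand <= F0_MAX:
            f0[i] = cand

    native_t = centers / w.rate
    out = resample_track_to_100hz(f0, native_t, w.duration, kind="nearest")
    out = zero_short_runs(out[:, 0], int(0.050 * FRAME_RATE))
    return FeatureTrack(out[:, None], ["f0"])


def f0_to_pitch(f0: float | np.ndarray, fs: float) -> float | np.ndarray:
    """Pitch period in samples: fs/f0 on voiced frames, 0 on unvoiced."""
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    f0_arr = np.asarray(f0, dtype=float)
    if np.any(f0_arr < 0):
        raise ValueError("F0 must be non-negative")
    out = np.zeros_like(f0_arr)
    np.divide(fs, f0_arr, out=out, where=f0_arr != 0)
    return out if isinstance(f0, np.ndarray) else float(out)


# ---------------------------------------------------------------------------
# synthesis

def _make_excitation(f0_per_sample: np.ndarray, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Impulse train at the running pitch period when voiced, white noise
    when unvoiced; both scaled to roughly unit power."""
    n = len(f0_per_sample)
    exc = np.zeros(n)
    unvoiced = f0_per_sample == 0
    exc[unvoiced] = rng.standard_normal(int(unvoiced.sum()))
    phase = 1.0  # emit an impulse at voicing onset
    for i in range(n):
        if f0_per_sample[i] == 0:
            phase = 1.0
            continue
        if phase >= 1.0:
            exc[i] = np.sqrt(fs / f0_per_sample[i])  # unit-power impulse train
            phase -= 1.0
        phase += f0_per_sample[i] / fs
    return exc


def mlsa_synthesize(
    mel: FeatureTrack, f0: FeatureTrack, seed: int | None = 0
) -> Waveform:
    """Synthesize audio from mel cepstrum + F0 (frequency-domain overlap-add).

    Per 220-sample frame the warped cepstrum is expanded to a linear-frequency
    amplitude response (same ``alpha`` as analysis) and applied to the
    excitation spectrum; frames are overlap-added with a Hann window.
    """
    if mel.n_frames != f0.n_frames:
        raise ValueError("mel and F0 tracks must have the same frame count")
    if mel.n_frames == 0:
        raise ValueError("empty tracks")
    if mel.n_frames < 2:
        raise ValueError("need at least two frames to synthesize")
    rng = np.random.default_rng(seed)
    fs = AUDIO_RATE
    n_samples = int(round(mel.n_frames / FRAME_RATE * fs))

    # per-sample F0 (nearest neighbour to preserve the voiced/unvoiced edges)
    frame_of_sample = np.clip(
        np.round(np.arange(n_samples) / fs * FRAME_RATE).astype(int), 0, f0.n_frames - 1
    )
    f0_per_sample = f0.data[frame_of_sample, 0]
    exc = _make_excitation(f0_per_sample, fs, rng)

    # per-synthesis-frame mel cepstra on the 220-hop grid
    centers = _frame_centers(n_samples)
    t_frames = centers / fs
    mc = PchipInterpolator(
        np.arange(mel.n_frames) / FRAME_RATE, mel.data, axis=0, extrapolate=True
    )(t_frames)

    n_bins = FFT_LEN // 2 + 1
    omega = np.linspace(0.0, np.pi, n_bins)
    theta_of_omega = _warp_forward(omega)
    amp = np.exp(_log_spectrum_from_cepstrum(mc, theta_of_omega))  # frames x bins

    half = FFT_LEN // 2
    pad = np.pad(exc, half, mode="constant")
    win = get_window("hann", FFT_LEN, fftbins=True)
    out = np.zeros(n_samples + FFT_LEN)
    norm = np.zeros(n_samples + FFT_LEN)
    for i, c in enumerate(centers):
        seg = pad[c : c + FFT_LEN] * win
        filt = np.fft.irfft(np.fft.rfft(seg) * amp[i])
        out[c : c + FFT_LEN] += filt
        norm[c : c + FFT_LEN] += win
    norm[norm < 1e-8] = 1.0
    y = (out / norm)[:n_samples]

    peak = np.max(np.abs(y))
    if peak == 0:
        raise ValueError("synthesis produced silence")
    y = y / peak
    # loudness to -20 dBFS, limited so the peak never exceeds full scale
    # (gain capped rather than waveform clipped, which would distort)
    gain = 10.0 ** (TARGET_RMS_DB / 20.0) / np.sqrt(np.mean(y**2))
    y = y * min(gain, 1.0)
    return Waveform(y, fs)
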