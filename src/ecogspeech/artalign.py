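"""Cross-speaker articulatory transfer via dynamic time warping.

The patient's articulatory trajectories were never recorded; they are
estimated by aligning each reference-speaker utterance onto the patient's
utterance of the same sentence, using DTW on acoustic features (normalized
mel cepstrum, normalized F0, and a binary speech flag), then dragging the
reference EMA trajectories through the warp path.

The sample-wise DTW distance is a sum of squared differences over the 27
feature values (25 mel + F0 + speech flag); both tracks are resampled to
the patient's length before alignment.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator
from sklearn.decomposition import PCA

from . import acoustics
from .tracks import FRAME_RATE, FeatureTrack, SentenceRecord

# 9-sensor EMA layout; the two lip-corner sensors move mostly
# latero-medially and are dropped before midsagittal projection
EMA_SENSORS = [
    "lip_corner_left",
    "lip_corner_right",
    "upper_lip",
    "lower_lip",
    "tongue_tip",
    "tongue_back",
    "tongue_dorsum",
    "velum",
    "jaw",
]
DROPPED_SENSORS = {"lip_corner_left", "lip_corner_right"}
KEPT_SENSORS = [s for s in EMA_SENSORS if s not in DROPPED_SENSORS]
EMA_LABELS = [f"{s}_{ax}" for s in KEPT_SENSORS for ax in ("x", "y")]
MIN_RUN_FRAMES = int(0.050 * FRAME_RATE)  # 50 ms misdetection filter


def project_midsagittal(ema3d: FeatureTrack) -> FeatureTrack:
    """Project 9-sensor 3-D EMA onto per-sensor 2-D principal planes.

    Drops the two lip-corner sensors, then for each remaining sensor
    centres its 3-D coordinates and keeps the first two principal axes,
    yielding 14 midsagittal features.
    """
    if ema3d.n_features != 27:
        raise ValueError("expected 9 sensors x 3 coordinates = 27 features")
    out = np.empty((ema3d.n_frames, 2 * len(KEPT_SENSORS)))
    col = 0
    for i, sensor in enumerate(EMA_SENSORS):
        if sensor in DROPPED_SENSORS:
            continue
        xyz = ema3d.data[:, 3 * i : 3 * i + 3]
        pca = PCA(n_components=2)
        out[:, col : col + 2] = pca.fit_transform(xyz)
        col += 2
    return FeatureTrack(out, list(EMA_LABELS))


def build_dtw_features(s: SentenceRecord) -> FeatureTrack:
    """27-value DTW feature track: normalized mel, normalized F0, speech flag.

    Mel coefficients are divided by the sentence's max ``|c0|``, F0 by its
    sentence maximum; the speech flag comes from envelope-based detection on
    the waveform (or a c0-energy proxy when no audio is attached).  Speech
    and voiced runs shorter than 50 ms are zeroed.
    """
    if "mel" not in s.tracks or "f0" not in s.tracks:
        raise ValueError("sentence needs mel and f0 tracks")
    mel = s.tracks["mel"].data
    f0 = s.tracks["f0"].data[:, 0]
    if mel.shape[0] == 0:
        raise ValueError("empty tracks")
    n = mel.shape[0]

    c0_max = np.max(np.abs(mel[:, 0]))
    mel_norm = mel / c0_max if c0_max > 0 else mel.copy()

    f0_filt = acoustics.zero_short_runs(f0, MIN_RUN_FRAMES)
    f0_max = np.max(f0_filt)
    f0_norm = f0_filt / f0_max if f0_max > 0 else f0_filt

    if s.waveform is not None:
        segs = acoustics.detect_speech(s.waveform)
        flag = acoustics.segments_to_flag(segs, n)
    else:
        # audio-free proxy: energy (c0) above 10% of its dynamic range
        c0 = mel[:, 0]
        flag = (c0 - c0.min() >= 0.10 * (c0.max() - c0.min())).astype(float)
    flag = acoustics.zero_short_runs(flag, MIN_RUN_FRAMES)

    data = np.column_stack([mel_norm, f0_norm, flag])
    labels = [f"dtw_{l}" for l in acoustics.MEL_LABELS] + ["dtw_f0", "dtw_speech"]
    return FeatureTrack(data, labels)


def resample_to_length(track: FeatureTrack, n: int) -> FeatureTrack:
    """Shape-preserving resampling to ``n`` uniformly spaced frames.

    The signal is padded by symmetrizing its sides before piecewise-cubic
    (pchip) interpolation, so the boundary slope estimates do not induce
    edge artifacts; endpoints are preserved exactly.
    """
    if n < 2:
        raise ValueError("need at least 2 output frames")
    m = track.n_frames
    if m < 2:
        raise ValueError("need at least 2 input frames")
    pad = min(3, m - 1)
    t = np.arange(-pad, m + pad, dtype=float)
    # point (odd) symmetrization: continues the boundary slope, so linear
    # trends survive and the boundary derivative estimates are unbiased
    left = 2 * track.data[0] - track.data[1 : pad + 1][::-1]
    right = 2 * track.data[m - 1] - track.data[m - pad - 1 : m - 1][::-1]
    padded = np.vstack([left, track.data, right])
    t_out = np.linspace(0.0, m - 1.0, n)
    out = PchipInterpolator(t, padded, axis=0)(t_out)
    return FeatureTrack(out, list(track.labels), track.rate)


def _pairwise_sqdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def dtw_align(
    ref: FeatureTrack, pat: FeatureTrack, use_sqrt: bool = False
) -> list[tuple[int, int]]:
    """Optimal monotone warp path between two equal-length feature tracks.

    Dynamic programming with steps {(1,0),(0,1),(1,1)} (ties prefer the
    diagonal), anchored at both ends.  The sample-wise cost is the sum of
    squared feature differences; ``use_sqrt=True`` switches to its square
    root for sensitivity checks.
    """
    if ref.n_frames != pat.n_frames:
        raise ValueError("tracks must be resampled to the same length before DTW")
    cost = _pairwise_sqdist(ref.data, pat.data)
    if use_sqrt:
        cost = np.sqrt(cost)
    n, m = cost.shape
    acc = np.full((n, m), np.inf)
    step = np.zeros((n, m), dtype=np.int8)  # 0=diag, 1=up(i-1), 2=left(j-1)
    acc[0, 0] = cost[0, 0]
    acc[0, 1:] = np.cumsum(cost[0, 1:]) + cost[0, 0]
    step[0, 1:] = 2
    acc[1:, 0] = np.cumsum(cost[1:, 0]) + cost[0, 0]
    step[1:, 0] = 1
    for i in range(1, n):
        prev, cur = acc[i - 1], acc[i]
        for j in range(1, m):
            diag, up, left = prev[j - 1], prev[j], cur[j - 1]
            best = diag
            s = 0
            if up < best:
                best, s = up, 1
            if left < best:
                best, s = left, 2
            cur[j] = cost[i, j] + best
            step[i, j] = s
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        s = step[i, j]
        if s == 0:
            i, j = i - 1, j - 1
        elif s == 1:
            i -= 1
        else:
            j -= 1
        path.append((i, j))
    path.reverse()
    return path


def path_cost(path: list[tuple[int, int]], ref: FeatureTrack, pat: FeatureTrack,
              use_sqrt: bool = False) -> float:
    d = ref.data[[i for i, _ in path]] - pat.data[[j for _, j in path]]
    c = np.einsum("ij,ij->i", d, d)
    if use_sqrt:
        c = np.sqrt(c)
    return float(c.sum())


def transfer_articulation(
    path: list[tuple[int, int]],
    ref_ema: FeatureTrack,
    target_len: int,
    aggregate: str = "mean",
) -> FeatureTrack:
    """Drag reference EMA through a warp path onto the patient's frame grid.

    For each patient frame ``j`` the estimate is the mean (or the last) of
    the reference frames paired with ``j`` in the path.
    """
    max_i = max(i for i, _ in path)
    max_j = max(j for _, j in path)
    if max_i >= ref_ema.n_frames or max_j >= target_len:
        raise ValueError("warp path inconsistent with track lengths")
    out = np.zeros((target_len, ref_ema.n_features))
    counts = np.zeros(target_len)
    for i, j in path:
        if aggregate == "mean":
            out[j] += ref_ema.data[i]
            counts[j] += 1
        elif aggregate == "last":
            out[j] = ref_ema.data[i]
            counts[j] = 1
        else:
            raise ValueError(f"unknown aggregation {aggregate!r}")
    if np.any(counts == 0):
        raise ValueError("warp path does not cover all patient frames")
    return FeatureTrack(out / counts[:, None], list(ref_ema.labels), ref_ema.rate)


def estimate_patient_ema(
    ref: SentenceRecord, pat: SentenceRecord, use_sqrt: bool = False
) -> tuple[FeatureTrack, list[tuple[int, int]]]:
    """Full transfer for one sentence pair: features -> DTW -> EMA transfer.

    Both DTW feature tracks and the reference EMA are first resampled to
    the patient's frame count, so the returned track is synchronized with
    the patient's audio and neural recordings.
    """
    if "ema" not in ref.tracks:
        raise ValueError("reference sentence carries no EMA track")
    ref_feats = build_dtw_features(ref)
    pat_feats = build_dtw_features(pat)
    m = pat_feats.n_frames
    ref_feats_rs = resample_to_length(ref_feats, m)
    path = dtw_align(ref_feats_rs, pat_feats, use_sqrt=use_sqrt)
    ref_ema_rs = resample_to_length(ref.tracks["ema"], m)
    est = transfer_articulation(path, ref_ema_rs, m)
    return est, path


def warp_reference_track(
    path: list[tuple[int, int]], ref_track: FeatureTrack, target_len: int
) -> FeatureTrack:
    """Warp any reference-speaker track onto the patient's timing."""
    return transfer_articulation(path, ref_track, target_len)


def path_to_ref_positions(path: list[tuple[int, int]], target_len: int) -> np.ndarray:
    """Mean reference index aligned to each patient frame (for warp error)."""
    pos = np.zeros(target_len)
    cnt = np.zeros(target_len)
    for i, j in path:
        pos[j] += i
        cnt[j] += 1
    return pos / np.maximum(cnt, 1)
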