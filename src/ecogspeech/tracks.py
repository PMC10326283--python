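"""Core containers shared by the whole pipeline.

Every feature stream (mel cepstrum, F0, articulatory trajectories, neural
band power) is represented as a :class:`FeatureTrack`: a frames x features
matrix sampled on a fixed uniform grid, 100 Hz by convention, with one label
per column.  Frame ``k`` covers the time centred at ``k / rate`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

FRAME_RATE = 100.0  # Hz, shared grid for all feature tracks


@dataclass
class Waveform:
    """Mono audio signal: float samples plus a sampling rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def write(self, path: str | Path) -> None:
        wavfile.write(str(path), int(self.rate), self.samples.astype(np.float32))

    @classmethod
    def read(cls, path: str | Path) -> "Waveform":
        rate, data = wavfile.read(str(path))
        data = np.asarray(data)
        if data.ndim > 1:
            data = data.mean(axis=1)
        if data.dtype.kind == "i":
            data = data / float(np.iinfo(data.dtype).max)
        return cls(samples=data.astype(float), rate=float(rate))


@dataclass
class FeatureTrack:
    """Frames x features matrix at a fixed rate with per-column labels."""

    data: np.ndarray
    labels: list[str]
    rate: float = FRAME_RATE

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.labels)} labels"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "FeatureTrack":
        return FeatureTrack(self.data.copy(), list(self.labels), self.rate)

    def select(self, columns: Sequence[int]) -> "FeatureTrack":
        cols = list(columns)
        return FeatureTrack(self.data[:, cols], [self.labels[c] for c in cols], self.rate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.labels)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def read(cls, path: str | Path, rate: float = FRAME_RATE) -> "FeatureTrack":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=float), list(df.columns), rate)


@dataclass
class SentenceRecord:
    """One utterance: identifiers, audio, and any attached feature tracks.

    ``tracks`` keys used by the pipeline: ``"mel"`` (25 cols), ``"f0"``
    (1 col), ``"ema"`` (14 cols), ``"neural"`` (raw multichannel is kept in
    ``neural_raw`` instead since it lives on its own sampling rate).
    """

    sentence_id: str
    text: str = ""
    condition: str = "read"
    speaker: str = "ref"
    waveform: Waveform | None = None
    tracks: dict[str, FeatureTrack] = field(default_factory=dict)
    neural_raw: "NeuralRecording | None" = None

    @property
    def n_frames(self) -> int:
        for t in self.tracks.values():
            return t.n_frames
        raise ValueError("sentence has no feature tracks")

    def with_tracks(self, **tracks: FeatureTrack) -> "SentenceRecord":
        new = dict(self.tracks)
        new.update(tracks)
        return replace(self, tracks=new)


@dataclass
class NeuralRecording:
    """Multichannel neural signal: channels x samples plus montage tags."""

    data: np.ndarray  # channels x samples
    rate: float
    montage: pd.DataFrame  # columns: channel_id, region

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] < 1:
            raise ValueError("need at least one channel")
        if len(self.montage) != self.data.shape[0]:
            raise ValueError("montage rows must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


def write_manifest(sentences: Sequence[SentenceRecord], path: str | Path) -> None:
    rows = [
        {
            "id": s.sentence_id,
            "text": s.text,
            "condition": s.condition,
            "speaker": s.speaker,
            "duration": s.waveform.duration if s.waveform is not None else np.nan,
        }
        for s in sentences
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
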