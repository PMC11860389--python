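"""Audio loading, resampling, validation and framing.

All downstream feature extraction operates on :class:`AudioSignal` objects
(mono, finite samples, known rate) framed with a 30 ms window and a 10 ms hop
by default, which matches the framing used throughout the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

DEFAULT_RATE = 16_000
DEFAULT_FRAME_MS = 30.0
DEFAULT_HOP_MS = 10.0

HEALTHY = "Healthy"
DEPRESSED = "Depressed"
LABELS = (HEALTHY, DEPRESSED)


class AudioLoadError(ValueError):
    """Raised when a file cannot be decoded into a usable signal."""


class FramingError(ValueError):
    """Raised when a signal is too short for the requested framing."""


@dataclass
class AudioSignal:
    """A mono speech recording with provenance metadata.

    Parameters
    ----------
    samples : ndarray
        Amplitude samples, float64, all finite.
    rate : int
        Sampling rate in Hz, strictly positive.
    source_id : str
        Opaque recording identifier.
    subject_id : str
        Opaque subject identifier (used for subject-independent folding).
    label : str or None
        Optional class tag, one of ``{"Healthy", "Depressed"}``.
    """

    samples: np.ndarray
    rate: int
    source_id: str = ""
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal stores mono signals only")
        if self.samples.size == 0:
            raise AudioLoadError("signal is empty")
        if not np.all(np.isfinite(self.samples)):
            raise AudioLoadError("signal contains non-finite samples")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.rate


@dataclass
class FrameSequence:
    """Fixed-length, hop-spaced windows cut from a signal.

    ``frames`` has shape ``(n_frames, frame_len)``; frames are raw
    (unwindowed) slices — spectral operations apply their own window.
    """

    frames: np.ndarray
    frame_len: int
    hop: int
    rate: int
    window: str = "none"

    def __post_init__(self) -> None:
        if self.frames.ndim != 2 or self.frames.shape[1] != self.frame_len:
            raise ValueError("frames must be (n_frames, frame_len)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame center timestamps in seconds."""
        starts = np.arange(self.n_frames) * self.hop
        return (starts + self.frame_len / 2.0) / self.rate


def n_frames_for(n_samples: int, frame_len: int, hop: int) -> int:
    """Closed-form frame count: floor((N - frame_len)/hop) + 1."""
    if n_samples < frame_len:
        raise FramingError(
            f"signal of {n_samples} samples shorter than one frame ({frame_len})"
        )
    return (n_samples - frame_len) // hop + 1


def load_audio(
    path: str | Path,
    target_rate: int = DEFAULT_RATE,
    *,
    source_id: str | None = None,
    subject_id: str = "",
    label: str | None = None,
) -> AudioSignal:
    """Read a PCM WAV file, average to mono and resample to ``target_rate``.

    Integer PCM is rescaled to [-1, 1] by the dtype's full scale; float WAVs
    are taken verbatim. Multi-channel input is averaged across channels.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - scipy raises assorted types
        raise AudioLoadError(f"cannot decode {path}: {exc}") from exc
    if data.size == 0:
        raise AudioLoadError(f"{path} decodes to zero samples")

    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(-np.iinfo(data.dtype).min, np.iinfo(data.dtype).max))
        x = data.astype(np.float64) / scale
    else:
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)

    if rate != target_rate:
        frac = Fraction(target_rate, int(rate)).limit_denominator(10_000)
        x = resample_poly(x, frac.numerator, frac.denominator)
    if not np.all(np.isfinite(x)):
        raise AudioLoadError(f"{path}: non-finite samples after resampling")
    return AudioSignal(
        samples=x,
        rate=target_rate,
        source_id=source_id if source_id is not None else path.stem,
        subject_id=subject_id,
        label=label,
    )


def save_audio(path: str | Path, signal: AudioSignal) -> None:
    """Write a signal as 16-bit PCM WAV (clipped to [-1, 1])."""
    x = np.clip(signal.samples, -1.0, 1.0)
    wavfile.write(Path(path), signal.rate, (x * 32767.0).astype(np.int16))


def frame_signal(
    signal: AudioSignal,
    frame_ms: float = DEFAULT_FRAME_MS,
    hop_ms: float = DEFAULT_HOP_MS,
) -> FrameSequence:
    """Slice a signal into contiguous fixed-length frames.

    Frame starts follow the arithmetic progression ``0, hop, 2*hop, ...``;
    trailing samples that do not fill a frame are dropped.
    """
    frame_len = int(round(signal.rate * frame_ms / 1000.0))
    hop = int(round(signal.rate * hop_ms / 1000.0))
    return frame_array(signal.samples, frame_len, hop, signal.rate)


def frame_array(
    x: np.ndarray, frame_len: int, hop: int, rate: int
) -> FrameSequence:
    """Frame a raw sample array (helper shared by the feature extractors)."""
    if frame_len <= 0 or hop <= 0:
        raise ValueError("frame_len and hop must be positive")
    count = n_frames_for(x.size, frame_len, hop)
    idx = np.arange(frame_len)[None, :] + hop * np.arange(count)[:, None]
    return FrameSequence(frames=x[idx], frame_len=frame_len, hop=hop, rate=rate)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a recording manifest CSV with columns path,subject,label[,task]."""
    df = pd.read_csv(path, dtype=str)
    required = {"path", "subject", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"manifest contains unknown labels: {sorted(bad)}")
    return df
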