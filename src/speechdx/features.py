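"""Handcrafted acoustic descriptors for depressed vs. healthy speech.

Three feature families, chosen so every dimension can be traced back to the
signal's structure:

* **MFCC** — 13 mel-frequency cepstral coefficients plus optional velocity
  and acceleration (temporal regression) coefficients; a condensed summary
  of the log mel spectrogram.
* **TEO-CB-Auto-Env** — per critical band, the area under the rectified
  normalized autocorrelation of the Teager-energy profile, a descriptor of
  speech produced under stress (16 bands spanning 100–7400 Hz).
* **F0 / HR** — fundamental frequency and harmonic ratio from the
  normalized autocorrelation, characterizing voiced/unvoiced structure.

All families share a single framing (30 ms / 10 ms by default) so their
matrices concatenate frame-aligned.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft
from scipy.signal import butter, sosfiltfilt

from .signal_io import (
    AudioSignal,
    FramingError,
    frame_array,
    frame_signal,
    DEFAULT_FRAME_MS,
    DEFAULT_HOP_MS,
)

LOG_FLOOR = 1e-10

#: Critical bands for the Teager-energy autocorrelation-envelope features:
#: (lower, center, upper) edges in Hz, 16 bands covering 100-7400 Hz.
CRITICAL_BANDS: tuple[tuple[float, float, float], ...] = (
    (100, 250, 400),
    (400, 500, 600),
    (600, 700, 800),
    (800, 910, 1020),
    (1020, 1140, 1260),
    (1260, 1400, 1540),
    (1540, 1690, 1840),
    (1840, 2000, 2160),
    (2160, 2350, 2540),
    (2540, 2750, 2960),
    (2960, 3200, 3440),
    (3440, 3720, 4000),
    (4000, 4310, 4620),
    (4620, 5010, 5400),
    (5400, 5850, 6300),
    (6300, 6850, 7400),
)


class FeatureError(ValueError):
    """Raised on invalid feature-extraction configuration or input."""


@dataclass
class FeatureMatrix:
    """A frames-by-dimensions descriptor matrix with timing metadata."""

    values: np.ndarray
    dim_names: list[str]
    frame_times: np.ndarray
    source_id: str = ""
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise FeatureError("values must be 2-D (frames x dims)")
        if self.values.shape[0] < 1:
            raise FeatureError("feature matrix needs at least one frame")
        if self.values.shape[1] != len(self.dim_names):
            raise FeatureError("dim_names length must match column count")
        if not np.all(np.isfinite(self.values)):
            raise FeatureError("feature matrix contains non-finite values")
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, columns=self.dim_names).assign(
            time_s=self.frame_times
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, source_id: str = "", subject_id: str = "",
        label: str | None = None,
    ) -> "FeatureMatrix":
        df = pd.read_csv(path)
        times = df.pop("time_s").to_numpy()
        return cls(df.to_numpy(), list(df.columns), times,
                   source_id=source_id, subject_id=subject_id, label=label)

    def to_npz(self, path: str | Path) -> None:
        """Compressed binary container with a metadata block."""
        meta = json.dumps(
            {"source_id": self.source_id, "subject_id": self.subject_id,
             "label": self.label, "dim_names": self.dim_names}
        )
        np.savez_compressed(path, values=self.values,
                            frame_times=self.frame_times, meta=meta)

    @classmethod
    def from_npz(cls, path: str | Path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(z["values"], meta["dim_names"], z["frame_times"],
                       source_id=meta["source_id"],
                       subject_id=meta["subject_id"], label=meta["label"])


@dataclass
class FeatureConfig:
    """Which descriptor families to extract, and their knobs."""

    use_mfcc: bool = True
    n_mfcc: int = 13
    use_delta: bool = True
    use_accel: bool = True
    use_teo: bool = False
    use_f0_hr: bool = False
    mel_filters: int = 26
    f0_range: tuple[float, float] = (50.0, 500.0)
    voicing_threshold: float = 0.3
    delta_window: int = 2
    frame_ms: float = DEFAULT_FRAME_MS
    hop_ms: float = DEFAULT_HOP_MS
    preset: str = "custom"

    def __post_init__(self) -> None:
        if self.n_mfcc < 1:
            raise FeatureError("n_mfcc must be >= 1")
        lo, hi = self.f0_range
        if not 0 < lo < hi:
            raise FeatureError(f"invalid f0_range {self.f0_range}")

    @classmethod
    def reading(cls) -> "FeatureConfig":
        """MFCC + velocity + acceleration (d = 39)."""
        return cls(use_mfcc=True, use_delta=True, use_accel=True,
                   use_teo=False, use_f0_hr=False, preset="reading")

    @classmethod
    def interview(cls) -> "FeatureConfig":
        """MFCC + velocity + TEO areas + F0/HR (d = 44)."""
        return cls(use_mfcc=True, use_delta=True, use_accel=False,
                   use_teo=True, use_f0_hr=True, preset="interview")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# MFCC

def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, rate: int,
                   fmin: float = 0.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, shape (n_filters, n_fft//2 + 1)."""
    if fmax is None:
        fmax = rate / 2.0
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    bins = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_filters, bins.size))
    for i in range(n_filters):
        left, center, right = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bins - left) / max(center - left, 1e-12)
        down = (right - bins) / max(right - center, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def compute_mfcc(signal: AudioSignal, config: FeatureConfig) -> FeatureMatrix:
    """Base mel-frequency cepstral coefficients, one row per frame.

    Each frame is Hamming-windowed, its power spectrum passed through a
    triangular mel filterbank, floored, logged and compressed with an
    orthonormal DCT-II. Coefficients 1..n_mfcc are kept (the 0th, a frame
    log-energy proxy, is dropped).
    """
    seq = frame_signal(signal, config.frame_ms, config.hop_ms)
    window = np.hamming(seq.frame_len)
    n_fft = seq.frame_len
    spectrum = np.abs(rfft(seq.frames * window, n=n_fft, axis=1)) ** 2
    fb = mel_filterbank(config.mel_filters, n_fft, signal.rate, 0.0, 8000.0)
    energies = spectrum @ fb.T
    log_e = np.log(np.maximum(energies, LOG_FLOOR))
    ceps = dct(log_e, type=2, norm="ortho", axis=1)
    vals = ceps[:, 1 : config.n_mfcc + 1]
    names = [f"mfcc_{i}" for i in range(1, config.n_mfcc + 1)]
    return FeatureMatrix(vals, names, seq.times, source_id=signal.source_id,
                         subject_id=signal.subject_id, label=signal.label)


def compute_delta(features: FeatureMatrix, order: str = "velocity",
                  window: int = 2) -> FeatureMatrix:
    """Regression-based temporal derivative of a feature matrix.

    Standard delta formula: slope of the least-squares line through
    ``2*window + 1`` frames; edges are padded by replication. ``order``
    "acceleration" applies the velocity operator twice.
    """
    if order not in ("velocity", "acceleration"):
        raise FeatureError(f"unknown delta order {order!r}")
    T = features.n_frames
    if T <= 2 * window + 1:
        raise FeatureError(
            f"need more than {2 * window + 1} frames for delta, got {T}"
        )

    def one_pass(x: np.ndarray) -> np.ndarray:
        padded = np.pad(x, ((window, window), (0, 0)), mode="edge")
        num = np.zeros_like(x)
        for n in range(1, window + 1):
            num += n * (padded[window + n : window + n + T]
                        - padded[window - n : window - n + T])
        return num / (2.0 * sum(n * n for n in range(1, window + 1)))

    out = one_pass(features.values)
    tag = "d"
    if order == "acceleration":
        out = one_pass(out)
        tag = "dd"
    names = [f"{tag}_{n}" for n in features.dim_names]
    return FeatureMatrix(out, names, features.frame_times,
                         source_id=features.source_id,
                         subject_id=features.subject_id, label=features.label)


# ---------------------------------------------------------------------------
# Teager-energy critical-band autocorrelation envelope

def teager_energy(x: np.ndarray) -> np.ndarray:
    """Teager energy operator Ψ[x](n) = x(n)² − x(n+1)·x(n−1).

    Output has the input's length; the two boundary values are replicated
    from their nearest interior neighbour.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise FeatureError("Teager operator needs at least 3 samples")
    core = x[1:-1] ** 2 - x[2:] * x[:-2]
    return np.concatenate(([core[0]], core, [core[-1]]))


def _band_filters(rate: int, order: int = 4):
    sos = []
    nyq = rate / 2.0
    for lo, _center, hi in CRITICAL_BANDS:
        hi_c = min(hi, nyq * 0.999)
        sos.append(butter(order, [lo / nyq, hi_c / nyq], btype="band",
                          output="sos"))
    return sos


def compute_teo_cb_env(signal: AudioSignal,
                       config: FeatureConfig | None = None) -> FeatureMatrix:
    """Per-band area under the autocorrelation envelope of the TEO profile.

    For each of the 16 critical bands: bandpass the signal (4th-order
    Butterworth, zero-phase), apply the Teager operator, frame the profile,
    and per frame integrate the rectified normalized autocorrelation over
    lags 0..L/2, dividing by L/2 (L = frame length). An all-zero frame
    yields 0.
    """
    config = config or FeatureConfig()
    frame_len = int(round(signal.rate * config.frame_ms / 1000.0))
    hop = int(round(signal.rate * config.hop_ms / 1000.0))
    half = frame_len // 2

    cols = []
    times = None
    for sos in _band_filters(signal.rate):
        band = sosfiltfilt(sos, signal.samples)
        profile = teager_energy(band)
        seq = frame_array(profile, frame_len, hop, signal.rate)
        frames = seq.frames
        if times is None:
            times = seq.times
        # normalized autocorrelation per frame over lags 0..half
        energy = np.sum(frames * frames, axis=1)
        areas = np.zeros(frames.shape[0])
        nz = energy > 0
        if np.any(nz):
            f = frames[nz]
            ac = np.empty((f.shape[0], half + 1))
            for lag in range(half + 1):
                if lag == 0:
                    ac[:, 0] = 1.0
                else:
                    ac[:, lag] = (np.sum(f[:, :-lag] * f[:, lag:], axis=1)
                                  / energy[nz])
            areas[nz] = np.sum(np.abs(ac), axis=1) / half
        cols.append(areas)
    vals = np.column_stack(cols)
    names = [f"teo_band_{i}" for i in range(1, 17)]
    return FeatureMatrix(vals, names, times, source_id=signal.source_id,
                         subject_id=signal.subject_id, label=signal.label)


# ---------------------------------------------------------------------------
# Fundamental frequency and harmonic ratio

def compute_f0_hr(signal: AudioSignal,
                  config: FeatureConfig | None = None) -> FeatureMatrix:
    """Pitch and harmonic ratio from the normalized autocorrelation.

    HR is the maximum of the normalized autocorrelation over the lag range
    implied by ``f0_range``; F0 = rate / (smallest near-maximal lag), which
    resolves the subharmonic ambiguity of periodic signals. Frames whose HR falls
    below the voicing threshold get F0 = 0 (unvoiced); all-zero frames get
    F0 = HR = 0.
    """
    config = config or FeatureConfig()
    seq = frame_signal(signal, config.frame_ms, config.hop_ms)
    lo, hi = config.f0_range
    if hi >= signal.rate / 2:
        raise FeatureError("f0_range upper edge must be below Nyquist")
    lag_min = max(1, int(np.floor(signal.rate / hi)))
    lag_max = int(np.ceil(signal.rate / lo))
    if lag_max >= seq.frame_len:
        raise FeatureError(
            f"frame of {seq.frame_len} samples shorter than max lag {lag_max}"
        )
    frames = seq.frames - seq.frames.mean(axis=1, keepdims=True)
    T = frames.shape[0]
    f0 = np.zeros(T)
    hr = np.zeros(T)
    for t in range(T):
        x = frames[t]
        e0 = float(x @ x)
        if e0 <= 0:
            continue
        lags = np.arange(lag_min, lag_max + 1)
        # normalized by the geometric mean of segment energies
        num = np.array([x[:-l] @ x[l:] for l in lags])
        den = np.sqrt(
            np.array([(x[:-l] @ x[:-l]) * (x[l:] @ x[l:]) for l in lags])
        )
        ok = den > 0
        if not np.any(ok):
            continue
        r = np.where(ok, num / np.maximum(den, 1e-300), -1.0)
        r_max = float(np.max(r))
        # periodic signals peak at every multiple of the period; take the
        # smallest near-maximal lag (avoids octave-down errors), then climb
        # to its local peak
        i = int(np.flatnonzero(r >= r_max - 1e-2)[0])
        while i + 1 < r.size and r[i + 1] > r[i]:
            i += 1
        while i > 0 and r[i - 1] > r[i]:
            i -= 1
        best = int(lags[i])
        hr[t] = max(0.0, r_max)
        if hr[t] >= config.voicing_threshold:
            f0[t] = signal.rate / best
    vals = np.column_stack([f0, hr])
    return FeatureMatrix(vals, ["f0_hz", "harmonic_ratio"], seq.times,
                         source_id=signal.source_id,
                         subject_id=signal.subject_id, label=signal.label)


# ---------------------------------------------------------------------------
# Assembly

def assemble_features(signal: AudioSignal,
                      config: FeatureConfig) -> FeatureMatrix:
    """Concatenate the enabled families into one frame-aligned matrix.

    The reading preset yields d = 39 (13 MFCC + 13 velocity +
    13 acceleration); the interview preset d = 44 (13 + 13 + 16 TEO + 2).
    """
    if not (config.use_mfcc or config.use_teo or config.use_f0_hr):
        raise FeatureError("at least one feature family must be enabled")
    blocks: list[FeatureMatrix] = []
    if config.use_mfcc:
        mfcc = compute_mfcc(signal, config)
        blocks.append(mfcc)
        if config.use_delta:
            blocks.append(compute_delta(mfcc, "velocity", config.delta_window))
        if config.use_accel:
            blocks.append(
                compute_delta(mfcc, "acceleration", config.delta_window)
            )
    if config.use_teo:
        blocks.append(compute_teo_cb_env(signal, config))
    if config.use_f0_hr:
        blocks.append(compute_f0_hr(signal, config))

    T = blocks[0].n_frames
    if any(b.n_frames != T for b in blocks):
        counts = [b.n_frames for b in blocks]
        raise FeatureError(f"family frame counts disagree: {counts}")
    values = np.hstack([b.values for b in blocks])
    names = [n for b in blocks for n in b.dim_names]
    return FeatureMatrix(values, names, blocks[0].frame_times,
                         source_id=signal.source_id,
                         subject_id=signal.subject_id, label=signal.label)
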