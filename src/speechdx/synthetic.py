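"""Synthetic corpora and deterministic audio fixtures.

Every pipeline stage is testable without external data:

* labeled feature-sequence corpora sampled from known class-specific
  GMM-HMM generators, with a *mean-shift* knob controlling class
  separation and a *persistence* knob making depressed-state patterns
  dwell longer (higher self-transition probability) than healthy ones;
* deterministic audio fixtures (pure tones, harmonic complexes, white
  noise, band-limited chirps, mid-stream switches) for the feature
  extractors;
* an audio rendering mode that turns sampled state paths into
  harmonic-plus-noise WAV signals so the full audio pipeline can run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .hmm_core import ERGODIC, GaussianMixture, HmmModel
from .signal_io import AudioSignal, DEPRESSED, HEALTHY, save_audio

DEFAULT_DIM = 8
DEFAULT_STATES = 2
#: default self-transition levels: depressed-speech states persist longer
DEFAULT_PERSISTENCE = {HEALTHY: 0.7, DEPRESSED: 0.9}


class GenerationError(ValueError):
    """Raised on infeasible generation requests."""


def _persistence_transitions(S: int, stay: float) -> np.ndarray:
    if not 0 < stay < 1:
        raise GenerationError(f"persistence must be in (0,1), got {stay}")
    A = np.full((S, S), (1.0 - stay) / max(S - 1, 1))
    np.fill_diagonal(A, stay if S > 1 else 1.0)
    return A


def make_class_generators(
    d: int = DEFAULT_DIM,
    n_states: int = DEFAULT_STATES,
    separation: float = 3.0,
    persistence: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[str, HmmModel]:
    """Build a Healthy/Depressed generator pair.

    Both share randomly placed, well-separated state means (unit
    variances); the depressed generator's means are shifted by
    ``separation`` along a fixed random direction and its states persist
    longer. ``separation=0`` with equal persistence yields identical
    generators (the null scenario).
    """
    if separation < 0:
        raise GenerationError("separation must be >= 0")
    persistence = persistence or dict(DEFAULT_PERSISTENCE)
    rng = np.random.default_rng(seed)
    base_means = rng.normal(scale=1.0, size=(n_states, d))
    base_means += np.arange(n_states)[:, None] * 4.0  # separate the states
    shift_dir = rng.normal(size=d)
    shift_dir /= np.linalg.norm(shift_dir)
    models = {}
    for cls in (HEALTHY, DEPRESSED):
        shift = separation * shift_dir if cls == DEPRESSED else 0.0
        pdfs = [
            GaussianMixture(np.array([1.0]), base_means[s] + shift,
                            np.ones((1, d)))
            for s in range(n_states)
        ]
        models[cls] = HmmModel(
            n_states=n_states,
            transitions=_persistence_transitions(n_states, persistence[cls]),
            initial=np.full(n_states, 1.0 / n_states),
            state_pdfs=pdfs,
            topology=ERGODIC,
        )
    return models


@dataclass
class SyntheticScenario:
    """The study conditions a synthetic corpus emulates."""

    n_subjects: int = 10          # per class
    recordings_per_subject: int = 3
    T: int = 150                  # frames per recording
    d: int = DEFAULT_DIM
    n_states: int = DEFAULT_STATES
    separation: float = 3.0
    persistence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PERSISTENCE))
    audio_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.recordings_per_subject < 1:
            raise GenerationError("need at least one subject and recording")
        for v in self.persistence.values():
            if not 0 < v < 1:
                raise GenerationError("persistence values must be in (0,1)")

    @classmethod
    def separable(cls, seed: int = 0, **kw) -> "SyntheticScenario":
        """Distant class generators: the task is solvable exactly."""
        return cls(separation=3.0, seed=seed, **kw)

    @classmethod
    def null(cls, seed: int = 0, **kw) -> "SyntheticScenario":
        """Identical generators: chance-level task (permutation control)."""
        return cls(separation=0.0,
                   persistence={HEALTHY: 0.8, DEPRESSED: 0.8},
                   seed=seed, **kw)

    def generators(self) -> dict[str, HmmModel]:
        return make_class_generators(
            d=self.d, n_states=self.n_states, separation=self.separation,
            persistence=self.persistence, seed=self.seed)


def sample_states(model: HmmModel, T: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Ancestral sampling of a state path."""
    states = np.empty(T, dtype=np.intp)
    states[0] = rng.choice(model.n_states, p=model.initial)
    for t in range(1, T):
        states[t] = rng.choice(model.n_states,
                               p=model.transitions[states[t - 1]])
    return states


def sample_hmm_sequences(model: HmmModel, n: int, T: int,
                         seed: int = 0) -> list[FeatureMatrix]:
    """Sample n feature sequences of length T from a GMM-HMM."""
    if n < 1 or T < 1:
        raise GenerationError("n and T must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    d = model.dim
    for i in range(n):
        states = sample_states(model, T, rng)
        X = np.empty((T, d))
        for t, s in enumerate(states):
            g = model.state_pdfs[s]
            k = rng.choice(g.n_components, p=g.weights)
            X[t] = rng.normal(g.means[k], np.sqrt(g.variances[k]))
        out.append(FeatureMatrix(
            X, [f"dim_{j}" for j in range(d)],
            frame_times=0.01 * np.arange(T), source_id=f"seq_{i}"))
    return out


@dataclass
class Corpus:
    """A labeled, subject-structured synthetic corpus."""

    manifest: pd.DataFrame
    features: dict[str, FeatureMatrix]
    ground_truth: dict


def make_corpus(scenario: SyntheticScenario,
                audio_dir: str | Path | None = None) -> Corpus:
    """Generate the corpus a scenario describes.

    Feature mode returns frame matrices sampled straight from the class
    generators. Audio mode additionally renders each recording's state path
    as harmonic-plus-noise audio (state-dependent F0 and noise level) and
    writes WAVs under ``audio_dir``.
    """
    rng = np.random.default_rng(scenario.seed)
    gens = scenario.generators()
    rows = []
    feats: dict[str, FeatureMatrix] = {}
    if scenario.audio_mode and audio_dir is not None:
        audio_dir = Path(audio_dir)
        audio_dir.mkdir(parents=True, exist_ok=True)
    for cls in (HEALTHY, DEPRESSED):
        model = gens[cls]
        tag = "h" if cls == HEALTHY else "p"
        for subj in range(scenario.n_subjects):
            subject_id = f"{tag}{subj:03d}"
            for rec in range(scenario.recordings_per_subject):
                source_id = f"{subject_id}_r{rec}"
                states = sample_states(model, scenario.T, rng)
                X = np.empty((scenario.T, scenario.d))
                for t, s in enumerate(states):
                    g = model.state_pdfs[s]
                    k = rng.choice(g.n_components, p=g.weights)
                    X[t] = rng.normal(g.means[k], np.sqrt(g.variances[k]))
                fm = FeatureMatrix(
                    X, [f"dim_{j}" for j in range(scenario.d)],
                    frame_times=0.01 * np.arange(scenario.T),
                    source_id=source_id, subject_id=subject_id, label=cls)
                feats[source_id] = fm
                path = ""
                if scenario.audio_mode and audio_dir is not None:
                    sig = render_states_as_audio(
                        states, seed=int(rng.integers(2**31)),
                        source_id=source_id, subject_id=subject_id,
                        label=cls)
                    path = str(audio_dir / f"{source_id}.wav")
                    save_audio(path, sig)
                rows.append({"path": path, "subject": subject_id,
                             "label": cls, "task": "synthetic",
                             "source_id": source_id})
    truth = {
        "separation": scenario.separation,
        "persistence": scenario.persistence,
        "n_states": scenario.n_states,
        "d": scenario.d,
        "transitions": {c: gens[c].transitions.tolist()
                        for c in (HEALTHY, DEPRESSED)},
        "means": {c: [g.means.tolist() for g in gens[c].state_pdfs]
                  for c in (HEALTHY, DEPRESSED)},
        "seed": scenario.seed,
    }
    return Corpus(manifest=pd.DataFrame(rows), features=feats,
                  ground_truth=truth)


# ---------------------------------------------------------------------------
# Audio fixtures

#: state-conditioned rendering parameters: fundamental (Hz), noise level
_STATE_VOICES = [(120.0, 0.02), (210.0, 0.05), (160.0, 0.1), (90.0, 0.01)]


def render_states_as_audio(states: np.ndarray, rate: int = 16_000,
                           hop_s: float = 0.01, seed: int = 0,
                           source_id: str = "", subject_id: str = "",
                           label: str | None = None) -> AudioSignal:
    """Render a state path as phase-continuous harmonic-plus-noise audio."""
    rng = np.random.default_rng(seed)
    hop = int(round(rate * hop_s))
    n = states.size * hop
    f0 = np.empty(n)
    noise_lvl = np.empty(n)
    for t, s in enumerate(states):
        freq, nz = _STATE_VOICES[int(s) % len(_STATE_VOICES)]
        f0[t * hop : (t + 1) * hop] = freq
        noise_lvl[t * hop : (t + 1) * hop] = nz
    phase = 2.0 * np.pi * np.cumsum(f0) / rate
    x = np.zeros(n)
    for h, amp in ((1, 0.5), (2, 0.25), (3, 0.12)):
        x += amp * np.sin(h * phase)
    x += noise_lvl * rng.standard_normal(n)
    x *= 0.8 / np.max(np.abs(x))
    return AudioSignal(x, rate, source_id=source_id, subject_id=subject_id,
                       label=label)


def make_audio_fixtures(kind: str, params: dict | None = None,
                        seed: int = 0) -> AudioSignal:
    """Deterministic audio fixtures for feature-extractor tests.

    Kinds: ``tone`` (freq_hz, amplitude, duration_s), ``harmonic``
    (f0_hz, n_harmonics, duration_s), ``noise`` (amplitude, duration_s),
    ``chirp`` (f_start_hz, f_end_hz, duration_s), ``switch``
    (first/second sub-fixture dicts and boundary_s).
    """
    p = dict(params or {})
    rate = int(p.pop("rate", 16_000))
    dur = float(p.pop("duration_s", 1.0))
    n = int(round(rate * dur))
    t = np.arange(n) / rate
    if kind == "tone":
        f = float(p.get("freq_hz", 200.0))
        a = float(p.get("amplitude", 0.5))
        if not 0 < f < rate / 2:
            raise GenerationError(f"tone frequency {f} out of range")
        x = a * np.sin(2 * np.pi * f * t)
    elif kind == "harmonic":
        f0 = float(p.get("f0_hz", 200.0))
        nh = int(p.get("n_harmonics", 5))
        if not 0 < f0 * nh < rate / 2:
            raise GenerationError("harmonics exceed Nyquist")
        x = sum((0.5 / h) * np.sin(2 * np.pi * h * f0 * t)
                for h in range(1, nh + 1))
    elif kind == "noise":
        a = float(p.get("amplitude", 0.3))
        x = a * np.random.default_rng(seed).standard_normal(n)
    elif kind == "chirp":
        from scipy.signal import chirp as _chirp

        f0 = float(p.get("f_start_hz", 100.0))
        f1 = float(p.get("f_end_hz", 4000.0))
        if not (0 < f0 < rate / 2 and 0 < f1 < rate / 2):
            raise GenerationError("chirp frequencies out of range")
        x = 0.5 * _chirp(t, f0, dur, f1)
    elif kind == "switch":
        boundary = float(p.get("boundary_s", dur / 2))
        first = make_audio_fixtures(
            p.get("first_kind", "tone"),
            {**p.get("first", {}), "duration_s": boundary, "rate": rate},
            seed)
        second = make_audio_fixtures(
            p.get("second_kind", "noise"),
            {**p.get("second", {}), "duration_s": dur - boundary,
             "rate": rate}, seed + 1)
        x = np.concatenate([first.samples, second.samples])
    else:
        raise GenerationError(f"unknown fixture kind {kind!r}")
    return AudioSignal(np.asarray(x, dtype=np.float64), rate,
                       source_id=f"{kind}_fixture")


def write_corpus(corpus: Corpus, out_dir: str | Path) -> None:
    """Persist manifest, feature CSVs and ground truth for audit."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus.manifest.to_csv(out / "manifest.csv", index=False)
    feat_dir = out / "features"
    feat_dir.mkdir(exist_ok=True)
    for sid, fm in corpus.features.items():
        fm.to_csv(feat_dir / f"{sid}.csv")
    (out / "ground_truth.json").write_text(
        json.dumps(corpus.ground_truth, indent=1))
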