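"""Universal model training and MAP mean adaptation into class models.

A single ergodic GMM-HMM (the *universal model* M) is trained on a balanced,
centric subset of both classes, so its parameters are estimated on pooled
data. Class-specific models then arise by maximum-a-posteriori adaptation of
M's Gaussian **means only**:

    μ̂_sk = N_sk / (N_sk + τ) · μ̄_sk  +  τ / (N_sk + τ) · μ_sk

where N_sk is the occupation likelihood of state s, component k on the
class's adaptation data, μ̄_sk the occupancy-weighted data mean, and τ a
relevance factor. Components the adaptation data never visits keep the
universal mean exactly; weights, variances, transitions and the initial
distribution are shared with M by construction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .data_selection import SelectionSplit
from .features import FeatureMatrix
from .hmm_core import (
    ERGODIC,
    HmmModel,
    HmmError,
    baum_welch,
    init_model,
    occupation_stats,
)
from .signal_io import DEPRESSED, HEALTHY

#: conventional relevance factor for MAP mean adaptation
DEFAULT_TAU = 16.0


class AdaptationError(ValueError):
    """Raised on invalid adaptation inputs."""


@dataclass
class UniversalModel:
    """The universal HMM M plus training provenance."""

    model: HmmModel
    training_ids: list[str]

    def __post_init__(self) -> None:
        if not self.training_ids:
            raise AdaptationError("universal model requires provenance ids")

    def digest(self) -> str:
        payload = json.dumps(self.model.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AdaptedPair:
    """Healthy/Depressed class models MAP-adapted from a shared parent."""

    healthy: HmmModel
    depressed: HmmModel
    tau: float
    parent_digest: str

    def model_for(self, label: str) -> HmmModel:
        if label == HEALTHY:
            return self.healthy
        if label == DEPRESSED:
            return self.depressed
        raise AdaptationError(f"unknown label {label!r}")


def train_ubm(
    split: SelectionSplit,
    features: dict[str, FeatureMatrix],
    S: int,
    K: int,
    topology: str = ERGODIC,
    seed: int = 0,
    max_iter: int = 25,
) -> UniversalModel:
    """Initialize and Baum-Welch-train M on the balanced centric subset."""
    train_ids = [i for ids in split.training_ids.values() for i in ids]
    missing = [i for i in train_ids if i not in features]
    if missing:
        raise AdaptationError(f"features missing for ids {missing}")
    seqs = [features[i] for i in train_ids]
    model = init_model(seqs, S, K, topology=topology, seed=seed)
    model = baum_welch(model, seqs, max_iter=max_iter)
    return UniversalModel(model=model, training_ids=train_ids)


def map_adapt(ubm: UniversalModel, adaptation_seqs: list[FeatureMatrix],
              tau: float = DEFAULT_TAU) -> HmmModel:
    """MAP-adapt the universal model's Gaussian means to class data.

    Only the means move: each μ̂_sk is the convex combination of the
    adaptation-data mean μ̄_sk (weight N_sk/(N_sk+τ)) and the universal
    mean μ_sk (weight τ/(N_sk+τ)). With τ = 0 every visited component's
    mean snaps to the data mean; as τ → ∞ the universal means persist.
    """
    if tau < 0:
        raise AdaptationError(f"tau must be non-negative, got {tau}")
    if not adaptation_seqs:
        raise AdaptationError("adaptation set is empty")
    stats = occupation_stats(ubm.model, adaptation_seqs)
    adapted = ubm.model.copy()
    for s, gmm in enumerate(adapted.state_pdfs):
        N = stats.occupation[s][:, None]           # (K, 1)
        data_mean = stats.data_means[s]            # (K, d)
        visited = stats.occupation[s] > 0
        alpha = np.where(N + tau > 0, N / (N + tau), 0.0)
        new_means = alpha * data_mean + (1.0 - alpha) * gmm.means
        gmm.means = np.where(visited[:, None], new_means, gmm.means)
    return adapted


def build_class_models(
    ubm: UniversalModel,
    split: SelectionSplit,
    features: dict[str, FeatureMatrix],
    tau: float = DEFAULT_TAU,
) -> AdaptedPair:
    """Derive the Healthy and Depressed models from the universal one."""
    models = {}
    for cls in (HEALTHY, DEPRESSED):
        ids = split.adaptation_ids.get(cls, [])
        if not ids:
            raise AdaptationError(f"no adaptation recordings for {cls}")
        models[cls] = map_adapt(ubm, [features[i] for i in ids], tau)
    return AdaptedPair(healthy=models[HEALTHY], depressed=models[DEPRESSED],
                       tau=tau, parent_digest=ubm.digest())


def save_pair(pair: AdaptedPair, out_dir) -> None:
    """Serialize both class models plus an audit manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pair.healthy.to_json(out / "model_healthy.json")
    pair.depressed.to_json(out / "model_depressed.json")
    (out / "manifest.json").write_text(json.dumps(
        {"tau": pair.tau, "parent_digest": pair.parent_digest}, indent=1))


def load_pair(in_dir) -> AdaptedPair:
    from pathlib import Path

    p = Path(in_dir)
    manifest = json.loads((p / "manifest.json").read_text())
    return AdaptedPair(
        healthy=HmmModel.from_json(p / "model_healthy.json"),
        depressed=HmmModel.from_json(p / "model_depressed.json"),
        tau=manifest["tau"],
        parent_digest=manifest["parent_digest"],
    )
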