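"""Correlation-based k-medoids organization of training vs. adaptation data.

Each class's recordings are compared pairwise with a canonical-correlation
distance (1 − first canonical correlation between the two feature
sequences), clustered with classic PAM (Partitioning Around Medoids), and
the most centric recordings — those closest to their medoid — are reserved
for training the universal model, balanced across classes; the rest feed
class-specific MAP adaptation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

#: ridge regularization scale for auto-covariances (times trace/d)
CCA_RIDGE = 1e-6


class SelectionError(ValueError):
    """Raised on infeasible selection requests."""


@dataclass
class DistanceMatrix:
    """Symmetric CCA-based distance matrix over recordings."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise SelectionError("distance matrix shape mismatch")


@dataclass
class SelectionSplit:
    """Per-class partition into universal-training and adaptation subsets."""

    training_ids: dict[str, list[str]]
    adaptation_ids: dict[str, list[str]]
    k_clusters: int
    train_fraction: float

    def to_dict(self) -> dict:
        return {
            "training_ids": self.training_ids,
            "adaptation_ids": self.adaptation_ids,
            "k_clusters": self.k_clusters,
            "train_fraction": self.train_fraction,
        }


def _center_truncate(X: np.ndarray, T: int) -> np.ndarray:
    """Middle T rows of X (avoids onset-silence bias)."""
    start = (X.shape[0] - T) // 2
    return X[start : start + T]


def cca_distance(f_i: FeatureMatrix | np.ndarray,
                 f_j: FeatureMatrix | np.ndarray) -> float:
    """1 minus the first canonical correlation between two feature sequences.

    Both sequences are truncated to their common (centered) length, centered,
    and the largest canonical correlation is extracted from the whitened
    cross-covariance via SVD, with a small ridge on the auto-covariances for
    conditioning. A zero-variance sequence is maximally dissimilar
    (distance 1).
    """
    X = f_i.values if isinstance(f_i, FeatureMatrix) else np.asarray(f_i, float)
    Y = f_j.values if isinstance(f_j, FeatureMatrix) else np.asarray(f_j, float)
    if X.shape[1] != Y.shape[1]:
        raise SelectionError("sequences must share dimensionality")
    T = min(X.shape[0], Y.shape[0])
    X = _center_truncate(X, T)
    Y = _center_truncate(Y, T)
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    Cxx = X.T @ X / T
    Cyy = Y.T @ Y / T
    Cxy = X.T @ Y / T
    d = X.shape[1]
    if np.trace(Cxx) <= 0 or np.trace(Cyy) <= 0:
        logger.warning("zero-variance sequence in CCA distance; returning 1")
        return 1.0
    Cxx = Cxx + CCA_RIDGE * np.trace(Cxx) / d * np.eye(d)
    Cyy = Cyy + CCA_RIDGE * np.trace(Cyy) / d * np.eye(d)
    Lx = linalg.cholesky(Cxx, lower=True)
    Ly = linalg.cholesky(Cyy, lower=True)
    M = linalg.solve_triangular(Lx, Cxy, lower=True)
    M = linalg.solve_triangular(Ly, M.T, lower=True).T
    rho = float(np.clip(linalg.svdvals(M)[0], 0.0, 1.0))
    return 1.0 - rho


def build_distance_matrix(features: list[FeatureMatrix]) -> DistanceMatrix:
    """All-pairs CCA distances (symmetry exploited, zero diagonal)."""
    n = len(features)
    if n < 2:
        raise SelectionError("need at least 2 recordings")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = cca_distance(features[i], features[j])
    return DistanceMatrix(ids=[f.source_id for f in features], values=D)


def euclidean_mean_distance_matrix(
    features: list[FeatureMatrix],
) -> DistanceMatrix:
    """Euclidean distances between per-recording mean feature vectors.

    The clustering-based alternative to the CCA distance, rescaled to [0, 1]
    by the maximum pairwise distance.
    """
    n = len(features)
    if n < 2:
        raise SelectionError("need at least 2 recordings")
    means = np.vstack([f.values.mean(axis=0) for f in features])
    diff = means[:, None, :] - means[None, :, :]
    D = np.sqrt(np.sum(diff * diff, axis=2))
    top = D.max()
    if top > 0:
        D = D / top
    return DistanceMatrix(ids=[f.source_id for f in features], values=D)


# ---------------------------------------------------------------------------
# PAM (Partitioning Around Medoids)

def pam_kmedoids(D: DistanceMatrix, k: int,
                 seed: int = 0) -> tuple[list[int], np.ndarray, float]:
    """Classic PAM: greedy BUILD then SWAP until no improving swap.

    Returns (medoid indices, point-to-cluster assignment, total cost).
    Deterministic: BUILD is greedy with lowest-index tie-breaks and SWAP
    scans candidates in index order, so the seed only labels the run.
    """
    n = len(D.ids)
    if not 1 <= k <= n:
        raise SelectionError(f"k={k} out of range for n={n}")
    dist = D.values

    # BUILD: first medoid minimizes total distance; then greedy additions
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    while len(medoids) < k:
        cur = dist[:, medoids].min(axis=1)
        gains = np.array([
            np.sum(np.maximum(cur - dist[:, c], 0.0)) if c not in medoids
            else -np.inf
            for c in range(n)
        ])
        medoids.append(int(np.argmax(gains)))

    def cost_of(meds: list[int]) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    best_cost = cost_of(medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                c = cost_of(trial)
                if c < best_cost - 1e-12:
                    medoids, best_cost = trial, c
                    improved = True
    assignment = np.argmin(dist[:, medoids], axis=1)
    return medoids, assignment, best_cost


def select_training_adaptation(
    features_by_class: dict[str, list[FeatureMatrix]],
    k: int = 2,
    train_fraction: float = 0.5,
    seed: int = 0,
    metric: str = "cca",
) -> SelectionSplit:
    """Split each class into centric UBM-training and adaptation subsets.

    Per class: distance matrix → PAM → rank members by distance to their
    medoid → the ``train_fraction`` most centric go to UBM training. The
    larger class's training set is then trimmed (least-centric dropped) so
    both classes contribute equally many recordings to the universal model.
    """
    if metric not in ("cca", "clustering"):
        raise SelectionError(f"unknown selection metric {metric!r}")
    ranked: dict[str, list[str]] = {}
    n_train: dict[str, int] = {}
    for cls, feats in features_by_class.items():
        if len(feats) < 2:
            raise SelectionError(f"class {cls!r} has < 2 recordings")
        k_eff = min(k, len(feats))
        builder = (build_distance_matrix if metric == "cca"
                   else euclidean_mean_distance_matrix)
        D = builder(feats)
        medoids, assign, _ = pam_kmedoids(D, k_eff, seed)
        to_medoid = D.values[np.arange(len(feats)),
                             [medoids[a] for a in assign]]
        order = np.argsort(to_medoid, kind="stable")  # most centric first
        ranked[cls] = [D.ids[i] for i in order]
        n_train[cls] = max(1, int(round(train_fraction * len(feats))))

    n_balanced = min(n_train.values())
    training, adaptation = {}, {}
    for cls, ids in ranked.items():
        training[cls] = ids[:n_balanced]
        adaptation[cls] = [i for i in ids if i not in set(training[cls])]
    return SelectionSplit(training_ids=training, adaptation_ids=adaptation,
                          k_clusters=k, train_fraction=train_fraction)
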