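"""Gaussian-mixture hidden Markov models.

A model is a tuple (S states, per-state diagonal-covariance Gaussian
mixtures, transition matrix A, initial distribution π) with an *ergodic*
(fully connected) or *left-right* (forward-only) topology. Inference runs
entirely in log space: forward/backward for likelihood and posteriors,
Viterbi for the most probable state path, Baum-Welch (EM) for training, and
forward-backward occupation statistics that feed maximum-a-posteriori mean
adaptation.

Transition convention: ``A[i, j]`` is the probability of moving from state
``i`` at time t to state ``j`` at time t+1 (row-stochastic).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture as _SkGMM

from .features import FeatureMatrix

ERGODIC = "ergodic"
LEFT_RIGHT = "left_right"
TOPOLOGIES = (ERGODIC, LEFT_RIGHT)

#: variance floor as a fraction of the global per-dimension variance
VAR_FLOOR_FRACTION = 1e-5
#: relative log-likelihood gain below which Baum-Welch stops
BW_TOL = 1e-6

_LOG_ZERO = -np.inf


class HmmError(ValueError):
    """Raised on invalid model structure or incompatible inputs."""


@dataclass
class GaussianMixture:
    """Diagonal-covariance Gaussian mixture p(x) = Σ_k w_k N(x; μ_k, σ²_k)."""

    weights: np.ndarray  # (K,)
    means: np.ndarray    # (K, d)
    variances: np.ndarray  # (K, d), already floored

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.variances = np.atleast_2d(
            np.asarray(self.variances, dtype=np.float64)
        )
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise HmmError(f"mixture weights sum to {self.weights.sum()}")
        if np.any(self.variances <= 0):
            raise HmmError("variances must be strictly positive")

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def component_log_pdf(self, X: np.ndarray) -> np.ndarray:
        """Per-component log density, shape (T, K) — weights not applied."""
        X = np.atleast_2d(X)
        diff = X[:, None, :] - self.means[None, :, :]  # (T, K, d)
        quad = np.sum(diff * diff / self.variances[None, :, :], axis=2)
        log_norm = -0.5 * (
            self.dim * np.log(2.0 * np.pi)
            + np.sum(np.log(self.variances), axis=1)
        )
        return log_norm[None, :] - 0.5 * quad

    def log_pdf(self, X: np.ndarray) -> np.ndarray:
        """Mixture log density per row of X, shape (T,)."""
        lw = np.log(np.maximum(self.weights, 1e-300))
        return logsumexp(self.component_log_pdf(X) + lw[None, :], axis=1)


def topology_mask(n_states: int, topology: str) -> np.ndarray:
    """Boolean mask of allowed transitions for a topology."""
    if topology == ERGODIC:
        return np.ones((n_states, n_states), dtype=bool)
    if topology == LEFT_RIGHT:
        return np.triu(np.ones((n_states, n_states), dtype=bool))
    raise HmmError(f"unknown topology {topology!r}")


@dataclass
class HmmModel:
    """A GMM-HMM with explicit topology."""

    n_states: int
    transitions: np.ndarray
    initial: np.ndarray
    state_pdfs: list[GaussianMixture]
    topology: str = ERGODIC
    feature_config_digest: str = ""

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        self.initial = np.asarray(self.initial, dtype=np.float64)
        S = self.n_states
        if self.transitions.shape != (S, S):
            raise HmmError("transition matrix shape mismatch")
        if np.any(np.abs(self.transitions.sum(axis=1) - 1.0) > 1e-9):
            raise HmmError("transition rows must sum to 1")
        if abs(self.initial.sum() - 1.0) > 1e-9:
            raise HmmError("initial distribution must sum to 1")
        if len(self.state_pdfs) != S:
            raise HmmError("need one mixture per state")
        mask = topology_mask(S, self.topology)
        if np.any(self.transitions[~mask] != 0.0):
            raise HmmError("transition matrix violates topology mask")

    @property
    def dim(self) -> int:
        return self.state_pdfs[0].dim

    @property
    def n_mixtures(self) -> int:
        return self.state_pdfs[0].n_components

    def copy(self) -> "HmmModel":
        return HmmModel(
            n_states=self.n_states,
            transitions=self.transitions.copy(),
            initial=self.initial.copy(),
            state_pdfs=[
                GaussianMixture(g.weights.copy(), g.means.copy(),
                                g.variances.copy())
                for g in self.state_pdfs
            ],
            topology=self.topology,
            feature_config_digest=self.feature_config_digest,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "topology": self.topology,
            "feature_config_digest": self.feature_config_digest,
            "transitions": self.transitions.tolist(),
            "initial": self.initial.tolist(),
            "state_pdfs": [
                {"weights": g.weights.tolist(), "means": g.means.tolist(),
                 "variances": g.variances.tolist()}
                for g in self.state_pdfs
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "HmmModel":
        return cls(
            n_states=d["n_states"],
            transitions=np.array(d["transitions"]),
            initial=np.array(d["initial"]),
            state_pdfs=[
                GaussianMixture(np.array(g["weights"]), np.array(g["means"]),
                                np.array(g["variances"]))
                for g in d["state_pdfs"]
            ],
            topology=d["topology"],
            feature_config_digest=d.get("feature_config_digest", ""),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "HmmModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class AdaptationStats:
    """Sufficient statistics of adaptation data under a reference model.

    ``occupation[s, k]`` is the expected number of frames generated by state
    s, component k (summed forward-backward posteriors); ``data_means`` the
    occupancy-weighted means of the adaptation observations.
    """

    occupation: np.ndarray   # (S, K)
    data_means: np.ndarray   # (S, K, d)
    n_sequences: int
    total_frames: int


# ---------------------------------------------------------------------------
# Inference

def _as_values(seq) -> np.ndarray:
    X = seq.values if isinstance(seq, FeatureMatrix) else np.atleast_2d(seq)
    return np.asarray(X, dtype=np.float64)


def _check_seq(model: HmmModel, X: np.ndarray) -> None:
    if X.shape[0] < 1:
        raise HmmError("empty sequence")
    if X.shape[1] != model.dim:
        raise HmmError(
            f"sequence dimension {X.shape[1]} != model dimension {model.dim}"
        )


def _log_params(model: HmmModel):
    with np.errstate(divide="ignore"):
        return np.log(model.transitions), np.log(model.initial)


def _emission_log_prob(model: HmmModel, X: np.ndarray) -> np.ndarray:
    """(T, S) matrix of per-state mixture log densities."""
    return np.column_stack([g.log_pdf(X) for g in model.state_pdfs])


def _forward(log_b, log_A, log_pi):
    T, S = log_b.shape
    alpha = np.empty((T, S))
    alpha[0] = log_pi + log_b[0]
    for t in range(1, T):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + log_A, axis=0) + log_b[t]
    return alpha


def _backward(log_b, log_A):
    T, S = log_b.shape
    beta = np.zeros((T, S))
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(log_A + (log_b[t + 1] + beta[t + 1])[None, :],
                            axis=1)
    return beta


def log_likelihood(model: HmmModel, seq) -> float:
    """Total observation log probability via the forward algorithm."""
    X = _as_values(seq)
    _check_seq(model, X)
    log_A, log_pi = _log_params(model)
    alpha = _forward(_emission_log_prob(model, X), log_A, log_pi)
    return float(logsumexp(alpha[-1]))


def viterbi_path(model: HmmModel, seq) -> tuple[np.ndarray, float]:
    """Most probable state path and its joint log probability.

    Ties are broken toward the lower state index.
    """
    X = _as_values(seq)
    _check_seq(model, X)
    log_b = _emission_log_prob(model, X)
    log_A, log_pi = _log_params(model)
    T, S = log_b.shape
    delta = log_pi + log_b[0]
    back = np.zeros((T, S), dtype=np.intp)
    for t in range(1, T):
        scores = delta[:, None] + log_A  # (from, to)
        back[t] = np.argmax(scores, axis=0)  # argmax -> first (lowest) index
        delta = scores[back[t], np.arange(S)] + log_b[t]
    path = np.empty(T, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path, float(np.max(delta))


def posteriors(model: HmmModel, seq) -> tuple[np.ndarray, np.ndarray, float]:
    """State posteriors γ (T, S), joint component posteriors (T, S, K), LL."""
    X = _as_values(seq)
    _check_seq(model, X)
    log_A, log_pi = _log_params(model)
    comp = np.stack(
        [g.component_log_pdf(X)
         + np.log(np.maximum(g.weights, 1e-300))[None, :]
         for g in model.state_pdfs], axis=1,
    )  # (T, S, K)
    log_b = logsumexp(comp, axis=2)
    alpha = _forward(log_b, log_A, log_pi)
    beta = _backward(log_b, log_A)
    ll = float(logsumexp(alpha[-1]))
    log_gamma = alpha + beta - ll
    gamma = np.exp(log_gamma)
    # within-state component responsibility
    resp = np.exp(comp - log_b[:, :, None])
    return gamma, gamma[:, :, None] * resp, ll


def occupation_stats(model: HmmModel, sequences: list) -> AdaptationStats:
    """Accumulate occupation likelihoods N_sk and data means over sequences.

    N_sk = Σ_r Σ_t L_sk,r(t) where L is the forward-backward posterior of
    (state s, component k) at time t; data means are the L-weighted averages
    of the observations. Conservation: Σ_s Σ_k N_sk equals the total frame
    count.
    """
    if not sequences:
        raise HmmError("no sequences given")
    S, K, d = model.n_states, model.n_mixtures, model.dim
    N = np.zeros((S, K))
    weighted = np.zeros((S, K, d))
    total = 0
    for seq in sequences:
        X = _as_values(seq)
        _, joint, _ = posteriors(model, X)
        N += joint.sum(axis=0)
        weighted += np.einsum("tsk,td->skd", joint, X)
        total += X.shape[0]
    means = np.where(N[:, :, None] > 0, weighted / np.maximum(N, 1e-300)[:, :, None], 0.0)
    return AdaptationStats(occupation=N, data_means=means,
                           n_sequences=len(sequences), total_frames=total)


# ---------------------------------------------------------------------------
# Initialization and training

def _fit_state_gmm(frames: np.ndarray, K: int, floor: np.ndarray,
                   seed: int, max_iter: int) -> GaussianMixture:
    if frames.shape[0] < 2 * K:
        # degenerate cluster: duplicate with jitter so EM has support
        rng = np.random.default_rng(seed)
        need = 2 * K - frames.shape[0]
        extra = frames[rng.integers(0, frames.shape[0], size=need)]
        extra = extra + rng.normal(scale=np.sqrt(floor), size=extra.shape)
        frames = np.vstack([frames, extra])
    gm = _SkGMM(n_components=K, covariance_type="diag", max_iter=max_iter,
                reg_covar=float(np.min(floor)), random_state=seed, n_init=1)
    gm.fit(frames)
    w = gm.weights_ / gm.weights_.sum()
    var = np.maximum(gm.covariances_, floor[None, :])
    return GaussianMixture(w, gm.means_, var)


def init_model(sequences: list, S: int, K: int, topology: str = ERGODIC,
               seed: int = 0, kmeans_iter: int = 50,
               gmm_iter: int = 25) -> HmmModel:
    """k-means state initialization with per-cluster EM mixture fits.

    Pooled frames are clustered into S groups (k-means, ≤50 iterations);
    each group's mixture is fitted by EM (≤25 iterations). Transitions and
    the initial distribution start uniform over the topology mask.
    """
    X = np.vstack([_as_values(s) for s in sequences])
    if X.shape[0] < S * K:
        raise HmmError(
            f"{X.shape[0]} frames cannot support {S} states x {K} mixtures"
        )
    floor = VAR_FLOOR_FRACTION * np.maximum(X.var(axis=0), 1e-12)
    if S == 1:
        labels = np.zeros(X.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=S, n_init=1, max_iter=kmeans_iter,
                    random_state=seed)
        labels = km.fit_predict(X)
    pdfs = []
    for s in range(S):
        frames = X[labels == s]
        if frames.shape[0] == 0:
            frames = X[np.random.default_rng(seed + s).integers(
                0, X.shape[0], size=max(2 * K, 2))]
        pdfs.append(_fit_state_gmm(frames, K, floor, seed + s, gmm_iter))
    mask = topology_mask(S, topology)
    A = mask / mask.sum(axis=1, keepdims=True)
    pi = np.full(S, 1.0 / S)
    return HmmModel(n_states=S, transitions=A, initial=pi, state_pdfs=pdfs,
                    topology=topology)


def baum_welch(model: HmmModel, sequences: list, max_iter: int = 25,
               tol: float = BW_TOL) -> HmmModel:
    """EM re-estimation of all HMM parameters over a set of sequences.

    Stops after ``max_iter`` iterations or when the relative gain in total
    log-likelihood falls below ``tol``. Topology-forbidden transitions stay
    exactly zero; variances are floored at a fraction of the global data
    variance.
    """
    if not sequences:
        raise HmmError("no training sequences")
    data = [_as_values(s) for s in sequences]
    for X in data:
        _check_seq(model, X)
    allX = np.vstack(data)
    floor = VAR_FLOOR_FRACTION * np.maximum(allX.var(axis=0), 1e-12)
    mask = topology_mask(model.n_states, model.topology)
    model = model.copy()
    S, K, d = model.n_states, model.n_mixtures, model.dim
    prev_ll = -np.inf
    for _ in range(max_iter):
        pi_acc = np.zeros(S)
        xi_acc = np.zeros((S, S))
        N = np.zeros((S, K))
        mean_acc = np.zeros((S, K, d))
        sq_acc = np.zeros((S, K, d))
        total_ll = 0.0
        log_A, log_pi = _log_params(model)
        for X in data:
            comp = np.stack(
                [g.component_log_pdf(X)
                 + np.log(np.maximum(g.weights, 1e-300))[None, :]
                 for g in model.state_pdfs], axis=1,
            )
            log_b = logsumexp(comp, axis=2)
            alpha = _forward(log_b, log_A, log_pi)
            beta = _backward(log_b, log_A)
            ll = float(logsumexp(alpha[-1]))
            total_ll += ll
            gamma = np.exp(alpha + beta - ll)
            pi_acc += gamma[0]
            T = X.shape[0]
            if T > 1:
                # ξ_t(i,j) summed over t in log space
                log_xi = (alpha[:-1, :, None] + log_A[None, :, :]
                          + (log_b[1:] + beta[1:])[:, None, :] - ll)
                xi_acc += np.exp(logsumexp(log_xi, axis=0))
            resp = np.exp(comp - log_b[:, :, None])
            joint = gamma[:, :, None] * resp
            N += joint.sum(axis=0)
            mean_acc += np.einsum("tsk,td->skd", joint, X)
            sq_acc += np.einsum("tsk,td->skd", joint, X * X)

        # M step
        model.initial = pi_acc / pi_acc.sum()
        A = np.where(mask, xi_acc, 0.0)
        rows = A.sum(axis=1, keepdims=True)
        # a state never left keeps its previous outgoing row
        dead = rows[:, 0] <= 0
        A = np.where(dead[:, None], model.transitions, A / np.maximum(rows, 1e-300))
        A = np.where(mask, A, 0.0)
        A /= A.sum(axis=1, keepdims=True)
        model.transitions = A
        for s in range(S):
            Ns = N[s]
            g = model.state_pdfs[s]
            w = Ns / np.maximum(Ns.sum(), 1e-300)
            mu = mean_acc[s] / np.maximum(Ns, 1e-300)[:, None]
            var = sq_acc[s] / np.maximum(Ns, 1e-300)[:, None] - mu * mu
            keep = Ns <= 1e-12
            mu = np.where(keep[:, None], g.means, mu)
            var = np.where(keep[:, None], g.variances, var)
            model.state_pdfs[s] = GaussianMixture(
                w / w.sum(), mu, np.maximum(var, floor[None, :])
            )
        if np.isfinite(prev_ll):
            gain = (total_ll - prev_ll) / max(abs(prev_ll), 1e-300)
            if gain < tol:
                break
        prev_ll = total_ll
    return model
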