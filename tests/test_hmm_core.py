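"""GMM-HMM inference and training against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from speechdx.hmm_core import (
    ERGODIC,
    LEFT_RIGHT,
    GaussianMixture,
    HmmError,
    HmmModel,
    baum_welch,
    init_model,
    log_likelihood,
    occupation_stats,
    posteriors,
    viterbi_path,
)
from speechdx.synthetic import make_class_generators, sample_hmm_sequences


# ---------------------------------------------------------------------------
# brute-force path enumeration oracle

def _path_log_prob(model, X, path):
    lp = np.log(model.initial[path[0]])
    lp += model.state_pdfs[path[0]].log_pdf(X[0:1])[0]
    for t in range(1, len(X)):
        lp += np.log(model.transitions[path[t - 1], path[t]])
        lp += model.state_pdfs[path[t]].log_pdf(X[t : t + 1])[0]
    return lp


def enumerate_paths(model, X):
    """All-path log probs keyed by path, in lexicographic order."""
    S, T = model.n_states, len(X)
    return {
        path: _path_log_prob(model, X, path)
        for path in itertools.product(range(S), repeat=T)
    }


class TestForwardOracle:
    def test_toy_model_matches_enumeration(self, toy_model, toy_sequence):
        table = enumerate_paths(toy_model, toy_sequence)
        expected = logsumexp(np.array(list(table.values())))
        assert log_likelihood(toy_model, toy_sequence) == pytest.approx(
            expected, abs=1e-9)

    def test_mixture_model_matches_enumeration(self, toy_model_mix):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 2)) * 2 + 2
        table = enumerate_paths(toy_model_mix, X)
        expected = logsumexp(np.array(list(table.values())))
        assert log_likelihood(toy_model_mix, X) == pytest.approx(
            expected, abs=1e-9)

    def test_single_state_closed_form(self):
        g = GaussianMixture(np.array([1.0]), np.array([[1.0]]),
                            np.array([[2.0]]))
        m = HmmModel(1, np.array([[1.0]]), np.array([1.0]), [g])
        X = np.array([[0.0], [1.0], [2.5]])
        expected = float(np.sum(g.log_pdf(X)))
        assert log_likelihood(m, X) == pytest.approx(expected, abs=1e-12)

    def test_matches_hmmlearn_reference(self, toy_model, toy_sequence):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag",
                                   init_params="")
        ref.startprob_ = toy_model.initial
        ref.transmat_ = toy_model.transitions
        ref.means_ = np.vstack([g.means for g in toy_model.state_pdfs])
        ref.covars_ = np.vstack([g.variances for g in toy_model.state_pdfs])
        assert log_likelihood(toy_model, toy_sequence) == pytest.approx(
            ref.score(toy_sequence), abs=1e-8)

    def test_errors(self, toy_model):
        with pytest.raises(HmmError):
            log_likelihood(toy_model, np.empty((0, 1)))
        with pytest.raises(HmmError):
            log_likelihood(toy_model, np.ones((3, 2)))


class TestViterbiOracle:
    def test_toy_model_matches_enumeration(self, toy_model, toy_sequence):
        table = enumerate_paths(toy_model, toy_sequence)
        # lexicographic iteration order makes max() break ties low-index
        best = max(table, key=lambda p: (table[p], [-s for s in p]))
        path, lp = viterbi_path(toy_model, toy_sequence)
        assert tuple(path) == best
        assert lp == pytest.approx(table[best], abs=1e-9)

    def test_mixture_model_matches_enumeration(self, toy_model_mix):
        X = np.random.default_rng(11).normal(size=(6, 2)) + 1.5
        table = enumerate_paths(toy_model_mix, X)
        best = max(table, key=lambda p: (table[p], [-s for s in p]))
        path, lp = viterbi_path(toy_model_mix, X)
        assert tuple(path) == best
        assert lp == pytest.approx(table[best], abs=1e-9)

    def test_single_state_trivial(self):
        g = GaussianMixture(np.array([1.0]), np.array([[0.0]]),
                            np.array([[1.0]]))
        m = HmmModel(1, np.array([[1.0]]), np.array([1.0]), [g])
        path, _ = viterbi_path(m, np.zeros((5, 1)))
        assert np.array_equal(path, np.zeros(5))

    def test_deterministic_cycle_forces_path(self):
        # A is a deterministic 2-cycle; emissions cannot override it
        pdfs = [GaussianMixture(np.array([1.0]), np.array([[m]]),
                                np.array([[1.0]])) for m in (0.0, 0.0)]
        m = HmmModel(2, np.array([[0.0, 1.0], [1.0, 0.0]]),
                     np.array([1.0, 0.0]), pdfs)
        path, _ = viterbi_path(m, 100.0 * np.ones((6, 1)))
        assert np.array_equal(path, [0, 1, 0, 1, 0, 1])


class TestOccupationStats:
    def test_single_state_pooled_mean(self):
        g = GaussianMixture(np.array([1.0]), np.array([[0.0]]),
                            np.array([[1.0]]))
        m = HmmModel(1, np.array([[1.0]]), np.array([1.0]), [g])
        seqs = [np.array([[1.0], [2.0]]), np.array([[3.0]])]
        stats = occupation_stats(m, seqs)
        assert stats.occupation[0, 0] == pytest.approx(3.0, abs=1e-12)
        assert stats.data_means[0, 0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_conservation(self, toy_model_mix):
        rng = np.random.default_rng(3)
        seqs = [rng.normal(size=(t, 2)) for t in (4, 7, 5)]
        stats = occupation_stats(toy_model_mix, seqs)
        assert stats.occupation.sum() == pytest.approx(16.0, abs=1e-6)
        assert np.all(stats.occupation >= 0)

    def test_matches_bruteforce_posteriors(self, toy_model, toy_sequence):
        table = enumerate_paths(toy_model, toy_sequence)
        lps = np.array(list(table.values()))
        total = logsumexp(lps)
        weights = np.exp(lps - total)
        T, S = len(toy_sequence), toy_model.n_states
        gamma = np.zeros((T, S))
        for w, path in zip(weights, table):
            for t, s in enumerate(path):
                gamma[t, s] += w
        stats = occupation_stats(toy_model, [toy_sequence])
        assert np.allclose(stats.occupation[:, 0], gamma.sum(axis=0),
                           atol=1e-9)
        # occupancy-weighted data means (K=1, so L = gamma)
        expected_means = (gamma.T @ toy_sequence) / gamma.sum(axis=0)[:, None]
        assert np.allclose(stats.data_means[:, 0, :], expected_means,
                           atol=1e-9)


class TestInitModel:
    def test_single_state_single_component(self):
        rng = np.random.default_rng(0)
        seqs = [rng.normal(loc=2.0, size=(50, 3)) for _ in range(2)]
        m = init_model(seqs, S=1, K=1, seed=0)
        pooled = np.vstack(seqs)
        assert np.allclose(m.transitions, [[1.0]])
        assert np.allclose(m.state_pdfs[0].means[0], pooled.mean(axis=0),
                           atol=1e-6)

    def test_left_right_mask(self):
        rng = np.random.default_rng(1)
        seqs = [rng.normal(size=(60, 2))]
        m = init_model(seqs, S=3, K=1, topology=LEFT_RIGHT, seed=1)
        assert np.all(m.transitions[np.tril_indices(3, -1)] == 0.0)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        seqs = [rng.normal(size=(80, 2))]
        a = init_model(seqs, S=2, K=2, seed=5)
        b = init_model(seqs, S=2, K=2, seed=5)
        assert np.array_equal(a.transitions, b.transitions)
        for ga, gb in zip(a.state_pdfs, b.state_pdfs):
            assert np.array_equal(ga.means, gb.means)

    def test_too_few_frames_errors(self):
        with pytest.raises(HmmError):
            init_model([np.ones((3, 2))], S=2, K=4)


class TestBaumWelch:
    def test_objective_monotone(self, toy_model):
        rng = np.random.default_rng(8)
        seqs = [rng.normal(size=(30, 1)) + (i % 2) * 3 for i in range(4)]
        lls = []
        m = toy_model
        for _ in range(6):
            m = baum_welch(m, seqs, max_iter=1, tol=0.0)
            lls.append(sum(log_likelihood(m, s) for s in seqs))
        assert all(b >= a - 1e-6 for a, b in zip(lls, lls[1:]))

    def test_left_right_preserved(self):
        rng = np.random.default_rng(4)
        seqs = [rng.normal(size=(40, 2)) + np.linspace(0, 4, 40)[:, None]
                for _ in range(3)]
        m = init_model(seqs, S=3, K=1, topology=LEFT_RIGHT, seed=0)
        trained = baum_welch(m, seqs, max_iter=5)
        assert np.all(trained.transitions[np.tril_indices(3, -1)] == 0.0)
        assert np.allclose(trained.transitions.sum(axis=1), 1.0, atol=1e-9)

    def test_recovers_transition_matrix(self):
        # data from a known 2-state model; entries recovered within 0.05
        truth = make_class_generators(d=2, n_states=2, separation=0.0,
                                      persistence={"Healthy": 0.9,
                                                   "Depressed": 0.9},
                                      seed=1)["Healthy"]
        truth.transitions = np.array([[0.9, 0.1], [0.2, 0.8]])
        seqs = [s.values for s in
                sample_hmm_sequences(truth, n=200, T=100, seed=2)]
        m0 = init_model(seqs, S=2, K=1, seed=0)
        m = baum_welch(m0, seqs, max_iter=25)
        # align states by best mean permutation
        true_means = np.vstack([g.means[0] for g in truth.state_pdfs])
        est_means = np.vstack([g.means[0] for g in m.state_pdfs])
        if (np.linalg.norm(est_means - true_means)
                > np.linalg.norm(est_means[::-1] - true_means)):
            perm = [1, 0]
        else:
            perm = [0, 1]
        A = m.transitions[np.ix_(perm, perm)]
        assert np.max(np.abs(A - truth.transitions)) < 0.05
        assert np.max(np.abs(est_means[perm] - true_means)) < 0.1

    def test_empty_sequence_list_errors(self, toy_model):
        with pytest.raises(HmmError):
            baum_welch(toy_model, [])


class TestSerialization:
    def test_json_roundtrip_bitstable(self, toy_model_mix, tmp_path):
        p = tmp_path / "m.json"
        toy_model_mix.to_json(p)
        back = HmmModel.from_json(p)
        assert np.array_equal(back.transitions, toy_model_mix.transitions)
        assert np.array_equal(back.initial, toy_model_mix.initial)
        for a, b in zip(back.state_pdfs, toy_model_mix.state_pdfs):
            assert np.array_equal(a.means, b.means)
            assert np.array_equal(a.variances, b.variances)
            assert np.array_equal(a.weights, b.weights)
        assert back.topology == toy_model_mix.topology

    def test_invariant_enforcement(self):
        g = GaussianMixture(np.array([1.0]), np.array([[0.0]]),
                            np.array([[1.0]]))
        with pytest.raises(HmmError):
            HmmModel(2, np.array([[0.5, 0.4], [0.5, 0.5]]),
                     np.array([0.5, 0.5]), [g, g])
        with pytest.raises(HmmError):
            GaussianMixture(np.array([0.9]), np.array([[0.0]]),
                            np.array([[1.0]]))
        with pytest.raises(HmmError):
            GaussianMixture(np.array([1.0]), np.array([[0.0]]),
                            np.array([[0.0]]))
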