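"""Shared fixtures: toy HMMs with printed parameters and small corpora."""

import numpy as np
import pytest

from speechdx.hmm_core import ERGODIC, GaussianMixture, HmmModel


@pytest.fixture
def toy_model():
    """2-state, 1-component, 1-D model with hand-printed parameters."""
    return HmmModel(
        n_states=2,
        transitions=np.array([[0.7, 0.3], [0.4, 0.6]]),
        initial=np.array([0.6, 0.4]),
        state_pdfs=[
            GaussianMixture(np.array([1.0]), np.array([[0.0]]),
                            np.array([[1.0]])),
            GaussianMixture(np.array([1.0]), np.array([[3.0]]),
                            np.array([[2.0]])),
        ],
        topology=ERGODIC,
    )


@pytest.fixture
def toy_model_mix():
    """3-state, 2-component, 2-D model exercising mixtures in inference."""
    rng = np.random.default_rng(7)
    pdfs = []
    for s in range(3):
        means = rng.normal(scale=2.0, size=(2, 2)) + 3.0 * s
        pdfs.append(GaussianMixture(np.array([0.4, 0.6]), means,
                                    np.full((2, 2), 1.5)))
    A = np.array([[0.6, 0.25, 0.15],
                  [0.2, 0.5, 0.3],
                  [0.3, 0.3, 0.4]])
    return HmmModel(n_states=3, transitions=A,
                    initial=np.array([0.5, 0.3, 0.2]), state_pdfs=pdfs,
                    topology=ERGODIC)


@pytest.fixture
def toy_sequence():
    """T=4 observation sequence for the 1-D toy model."""
    return np.array([[0.5], [2.8], [3.1], [-0.2]])
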