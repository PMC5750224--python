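import numpy as np
import pytest

from vampnet import LaggedDataset, sample_markov_chain

#: Reversible 2-state chain used throughout: stationary pi = (2/3, 1/3),
#: second eigenvalue 1 - 0.1 - 0.2 = 0.7, so the full mean-free VAMP-2
#: score with the constant augmentation is 1 + 0.7^2 = 1.49.
P_TWO_STATE = np.array([[0.9, 0.1], [0.2, 0.8]])
PI_TWO_STATE = np.array([2.0 / 3.0, 1.0 / 3.0])
LAMBDA2 = 0.7


def chain_onehot(P: np.ndarray, n_steps: int, seed: int) -> np.ndarray:
    """One-hot (indicator) encoded sample path of a discrete chain."""
    states = sample_markov_chain(P, n_steps, seed)
    return np.eye(P.shape[0])[states]


@pytest.fixture(scope="session")
def two_state_dataset() -> LaggedDataset:
    """50,000-step one-hot trajectory of the 2-state chain at lag 1."""
    return LaggedDataset.from_trajectory(chain_onehot(P_TWO_STATE, 50_000, seed=1), lag=1)
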