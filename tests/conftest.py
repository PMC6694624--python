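import numpy as np
import pytest

from anmf.data_io import Dataset


def make_dataset(R: np.ndarray, rng: np.random.Generator | None = None) -> Dataset:
    """Wrap a binary matrix in a Dataset with valid random similarity matrices."""
    rng = rng or np.random.default_rng(0)
    R = np.asarray(R, dtype=float)
    m, n = R.shape

    def sim(size):
        S = rng.uniform(0, 1, (size, size))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        return S

    return Dataset(
        drug_ids=[f"drug{i}" for i in range(m)],
        disease_ids=[f"dis{j}" for j in range(n)],
        R=np.asarray(R, dtype=float),
        drug_sim=sim(m),
        disease_sim=sim(n),
    ).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """4 drugs x 4 diseases with a mix of row counts."""
    R = np.array([
        [1, 0, 0, 0],
        [1, 1, 0, 0],
        [0, 1, 1, 1],
        [0, 0, 0, 1],
    ], dtype=float)
    return make_dataset(R)
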