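import numpy as np
import pytest

from hconnica import Connectome, Modality


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_symmetric(n, rng, low=-1.0, high=1.0):
    m = rng.uniform(low, high, (n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


@pytest.fixture
def random_fc(rng):
    return Connectome(
        matrix=random_symmetric(10, rng),
        modality=Modality.FC,
        subject_id="S1",
        condition="REST",
    )


def make_sc(matrix, subject_id="S1"):
    return Connectome(
        matrix=np.asarray(matrix, float),
        modality=Modality.SC_RAW,
        subject_id=subject_id,
    )


def sc_from_edges(n, edges, weight=1.0, subject_id="S1"):
    m = np.zeros((n, n))
    for (i, j) in edges:
        m[i, j] = m[j, i] = weight
    return make_sc(m, subject_id=subject_id)
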