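import numpy as np
import pytest

from nabind.model import ModelConfig, train
from nabind.synthetic import (ToySpec, default_toy_suite,
                              generate_synthetic_dataset,
                              generate_toy_complex)


@pytest.fixture(scope="session")
def toy_dsdna():
    """Peptide bound to a B-form DNA duplex."""
    structure, text = generate_toy_complex(ToySpec(10, "dsDNA", 6, 4.0, 1))
    return structure, text


@pytest.fixture(scope="session")
def toy_ssrna():
    structure, text = generate_toy_complex(ToySpec(10, "ssRNA", 6, 4.0, 2))
    return structure, text


@pytest.fixture(scope="session")
def toy_suite():
    return default_toy_suite(0)


@pytest.fixture(scope="session")
def small_synthetic(toy_suite):
    """Small synthetic affinity dataset with known generative coefficients."""
    return generate_synthetic_dataset(toy_suite, n_records=60, seed=11,
                                      noise_sigma=0.2)


@pytest.fixture(scope="session")
def small_model(small_synthetic):
    """Extremely-randomized-trees model trained on the small synthetic set."""
    config = ModelConfig(hyperparameters={"n_estimators": 60}, random_seed=0)
    y = [r.ddg for r in small_synthetic.dataset]
    return train(small_synthetic.features, y, config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """A random proper rotation matrix and translation vector."""
    g = np.random.default_rng(seed)
    m = g.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, g.normal(scale=10.0, size=3)


def transform_structure(structure, rot, trans):
    moved = structure.copy()
    for a in moved.atoms:
        a.position = rot @ a.position + trans
    return moved
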