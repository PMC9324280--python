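import numpy as np
import pytest

from radstab.data_model import FeatureTable, ReplicatePair
from radstab.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    return FeatureTable(
        ["s1", "s2", "s3"],
        ["f|a|x", "f|a|y"],
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        np.array([0, 1, 1]),
        "tiny",
    )


@pytest.fixture(scope="session")
def planted_pair():
    """Small cohort with 5 planted informative features among noise."""
    cfg = SyntheticConfig(
        n_samples=150,
        n_features=60,
        n_informative=5,
        effect_sizes=(2.0, 1.75, 1.5, 1.25, 1.0),
        block_structure=((8, 0.5),) * 3,
        replicate_noise_sd=0.1,
        seed=7,
    )
    pair, labels = generate_cohort(cfg)
    return cfg, pair, labels


@pytest.fixture(scope="session")
def _warm_solver():
    # trigger numba compilation once so per-test timings stay honest
    from radstab._enet import enet_logistic

    X = np.random.default_rng(0).standard_normal((20, 3))
    y = (X[:, 0] > 0).astype(float)
    enet_logistic(X, y, 0.1, 0.5)
    return True
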