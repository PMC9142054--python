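import numpy as np
import pytest

from kefrin import FeatureMatrix, GeneratorConfig, NetworkMatrix, generate


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def tiny_features():
    return FeatureMatrix(
        values=np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 3.0]]),
        node_ids=["a", "b", "c"],
        feature_names=["f1", "f2"],
        feature_kinds=["quantitative", "quantitative"],
    )


@pytest.fixture
def tiny_network():
    return NetworkMatrix(
        values=np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]]),
        node_ids=["a", "b", "c"],
    )


@pytest.fixture(scope="session")
def easy_dataset():
    """Two well-separated planted blocks in both spaces."""
    config = GeneratorConfig(
        n=60, k=2, p=0.95, q=0.05, alpha=0.95, min_size=20, v_quant=4, rng_seed=42
    )
    return generate(config, flavor="quantitative")


def random_instance(rng, n=20, k=3, v=4):
    """Small random (Y, P) pair for oracle comparisons."""
    Y = rng.standard_normal((n, v))
    P = rng.standard_normal((n, n))
    return Y, P
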