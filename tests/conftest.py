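import numpy as np
import pytest

from subgolgi import (
    FeatureMatrix,
    Motif,
    RfConfig,
    SyntheticSpec,
    encode_dataset,
    generate,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def planted_dataset():
    """100/100 two-class dataset with a strong FP 2-gap motif in trans."""
    spec = SyntheticSpec(
        n_cis=100,
        n_trans=100,
        motifs=(Motif("F", "P", k=2, excess_rate=0.15, label="trans"),),
        seed=1,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def planted_kgap_matrix(planted_dataset):
    return encode_dataset(planted_dataset, ("kgapdc",))


@pytest.fixture(scope="session")
def small_rf():
    """Forest config small enough for per-fold refits in tests."""
    return RfConfig(n_trees=100, seed=7)


def toy_separable_matrix(n_per_class: int = 10, n_features: int = 5, seed: int = 0):
    """Labeled matrix whose first feature perfectly separates the classes."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    values = rng.random((n, n_features))
    values[:n_per_class, 0] = rng.uniform(0.0, 0.2, n_per_class)
    values[n_per_class:, 0] = rng.uniform(0.8, 1.0, n_per_class)
    labels = ["cis"] * n_per_class + ["trans"] * n_per_class
    return FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        feature_names=[f"f{j}" for j in range(n_features)],
        values=values,
        labels=labels,
    )
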