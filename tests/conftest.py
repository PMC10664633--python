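import numpy as np
import pytest
from hypothesis import settings

import ddafuse as d
from ddafuse.pair_features import PROV_OBSERVED, PairFeatureTable
from ddafuse.pipeline import fuse_views

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


def make_table(X: np.ndarray, y: np.ndarray) -> PairFeatureTable:
    """Wrap bare arrays in a pair table (for classifier/balance tests)."""
    r = len(y)
    return PairFeatureTable(
        drug_ids=np.array([f"dr{i}" for i in range(r)], dtype=object),
        disease_ids=np.array([f"di{i}" for i in range(r)], dtype=object),
        labels=np.asarray(y, dtype=np.int8),
        features=np.asarray(X, dtype=float),
        provenance=np.full(r, PROV_OBSERVED, dtype=object),
    )


@pytest.fixture(scope="session")
def small_data():
    """20 drugs x 15 diseases with planted 3x3 group structure."""
    return d.generate(d.SyntheticConfig(m=20, n=15, G=3, H=3, seed=3))


@pytest.fixture(scope="session")
def small_fused(small_data):
    cfg = d.SNFConfig(K=5, T=10)
    return (
        fuse_views(small_data.drug_profiles, cfg),
        fuse_views(small_data.disease_profiles, cfg),
    )


@pytest.fixture(scope="session")
def small_table(small_data, small_fused):
    udrs, udis = small_fused
    return d.build_pair_table(udrs, udis, small_data.assoc)


@pytest.fixture()
def blob_table():
    """Linearly separable two-blob table (400 rows, 8 features)."""
    rng = np.random.default_rng(42)
    n = 200
    X0 = rng.normal(-2.0, 0.6, size=(n, 8))
    X1 = rng.normal(2.0, 0.6, size=(n, 8))
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    perm = rng.permutation(2 * n)
    return make_table(X[perm], y[perm])


def random_symmetric(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric non-negative similarity-like matrix, unit diagonal."""
    A = rng.random((n, n))
    W = (A + A.T) / 2.0
    np.fill_diagonal(W, 1.0)
    return W
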