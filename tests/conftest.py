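import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fava import (
    FixtureSpec,
    ScoredNetwork,
    VAEConfig,
    generate_fixture,
    preprocess,
    train_vae,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SMALL_SPEC = FixtureSpec(
    n_modules=2,
    genes_per_module=10,
    n_background_genes=5,
    n_cell_clusters=4,
    cells_per_cluster=25,
    dropout_rate=0.5,
    redundancy_factor=2,
    seed=42,
)


@pytest.fixture(scope="session")
def small_fixture():
    """25 genes x 200 cells with two planted modules; quick to train on."""
    return generate_fixture(SMALL_SPEC)


@pytest.fixture(scope="session")
def trained_latent(small_fixture):
    matrix, _ = small_fixture
    cfg = VAEConfig(hidden_dim=64, latent_dim=8, epochs=150, seed=7)
    return train_vae(preprocess(matrix), cfg)


@pytest.fixture()
def random_network():
    """Deterministic 20-gene fully-connected network with random scores."""
    rng = np.random.default_rng(11)
    genes = [f"g{i:02d}" for i in range(20)]
    pairs = [
        (genes[i], genes[j], rng.uniform(-1, 1))
        for i in range(20)
        for j in range(i + 1, 20)
    ]
    return ScoredNetwork.from_pairs(pairs)
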