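import numpy as np
import pytest

from toxsig.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Scaled-down benchmark: fast enough for unit tests, same structure."""
    return SyntheticConfig(
        n_compounds=400,
        n_proteins=80,
        n_assays=3,
        n_pathways=12,
        pathway_size_range=(6, 14),
        n_causal_proteins=8,
        n_causal_pathways=2,
        bit_pool_size=128,
        causal_pool_size=40,
        n_scaffolds=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
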