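import numpy as np
import pytest

from breedsim import (
    FounderConfig,
    LocusMap,
    OverlapScheme,
    build_architecture,
    generate_founders,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_map():
    """A 300-locus, 3-chromosome map for unit tests."""
    return LocusMap.regular(300, 3, 10_000_000, np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_arch(small_map):
    """An architecture with 31 QTL per trait-environment on the small map."""
    scheme = OverlapScheme(n_per_trait_env=31)
    return build_architecture(scheme, small_map, np.random.default_rng(8))


@pytest.fixture(scope="session")
def small_founders(small_map, small_arch):
    cfg = FounderConfig(n_existing=120, n_external=30)
    return generate_founders(cfg, small_map, small_arch, np.random.default_rng(9))
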