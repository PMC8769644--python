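import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from innexscan.synthetic import SimConfig, TaxonSpec, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Two clean taxa, no planted rejects: 12 four-TM proteins."""
    return SimConfig(
        seed=101,
        taxa=(
            TaxonSpec("alpha", n_species=3, isoforms_min=2, isoforms_max=2,
                      p_el_ngs=1.0),
            TaxonSpec("beta", n_species=3, isoforms_min=2, isoforms_max=2,
                      p_el_ngs=0.5),
        ),
        decoy_fraction=0.0, fragment_fraction=0.0, duplicate_fraction=0.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def messy_dataset():
    """Dataset with planted decoys, fragments and duplicates."""
    cfg = SimConfig(
        seed=202,
        taxa=(
            TaxonSpec("gamma", n_species=6, isoforms_min=3, isoforms_max=6,
                      p_el_ngs=0.7),
        ),
        decoy_fraction=0.15, fragment_fraction=0.1, duplicate_fraction=0.1,
    )
    return cfg, simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
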