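from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def table1():
    """The published worked-example bundle:
    (genotypes, popmap, catalog, gene_models, cds_seqs)."""
    from resistscan.simulate import table1_fixture

    return table1_fixture()


@pytest.fixture(scope="session")
def reference():
    """Synthetic assembly gene models and CDS sequences."""
    from resistscan.simulate import synthetic_reference

    return synthetic_reference()


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)


def random_calls(rng, n_sites, n_samples, miss_rate=0.05):
    """Random genotype matrix calls with missingness (helper, not a test)."""
    calls = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    calls[rng.random((n_sites, n_samples)) < miss_rate] = -1
    return calls
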