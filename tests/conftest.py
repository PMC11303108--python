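import numpy as np
import pytest

from tfgate.scrna_stage import DEGConfig
from tfgate.synthetic_data import SimConfig, generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle, seed 0 — shared read-only across tests."""
    return generate_bundle(SimConfig(seed=0))


@pytest.fixture(scope="session")
def deg_config(bundle):
    return DEGConfig(tf_gene_id=bundle.truth.tf_gene_id)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
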