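import numpy as np
import pytest

from tfnet.config import SynthConfig
from tfnet.synth import (
    generate_expression,
    generate_go_and_regulatory,
    generate_inventory,
)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(n_genes_per_family=10, seed=11)


@pytest.fixture(scope="session")
def inventory_bundle(small_config):
    return generate_inventory(small_config)


@pytest.fixture(scope="session")
def expression_bundle(small_config, inventory_bundle):
    return generate_expression(small_config, inventory_bundle)


@pytest.fixture(scope="session")
def go_reg_bundle(small_config, inventory_bundle, expression_bundle):
    _, truth = expression_bundle
    return generate_go_and_regulatory(
        small_config, inventory_bundle, truth["de_signs"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
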