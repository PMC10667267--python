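import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from netpharm import GeneratorConfig, generate_bundle
from netpharm.screening import DescriptorSet


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic study at the default (paper-scale) configuration."""
    return generate_bundle(GeneratorConfig(seed=20231123))


@pytest.fixture
def druglike_descriptors():
    """A descriptor vector squarely inside the drug-like ranges."""
    return DescriptorSet(mw=350.0, alogp=2.5, hba=4, hbd=1, tpsa=80.0,
                         rotb=4, arom=2, alerts=0)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down generator config for fast per-stage tests."""
    return GeneratorConfig(seed=7, n_compounds=12, universe_size=400,
                           n_disease_genes=40, n_overlap=10, n_hubs=4,
                           predicted_pool_size=120, n_pathways=15,
                           compound_target_rate=12)
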