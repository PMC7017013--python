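import logging

import pytest

from prodomainkit import simulate_family
from prodomainkit.synth import SyntheticConfig

logging.getLogger("prodomainkit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_family():
    """One default synthetic family shared by read-only tests."""
    return simulate_family(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_family():
    """A small, fast family for alignment/tree tests."""
    cfg = SyntheticConfig(seed=3, members_per_subfamily=5,
                          plant_convergent_pair=False)
    return simulate_family(cfg)
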