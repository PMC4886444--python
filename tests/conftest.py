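import logging

import pytest

from ssbstroke import SyntheticConfig, TaxScenario, generate_bundle

logging.getLogger("ssbstroke").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundle():
    """Default full-size synthetic bundle (17 age bands x 2 sexes)."""
    return generate_bundle(SyntheticConfig(seed=12345))


@pytest.fixture(scope="session")
def small_bundle():
    """Four mid-life age bands; fast enough for repeated pipeline runs."""
    groups = tuple(f"{lo}-{lo + 4}" for lo in range(40, 60, 5))
    return generate_bundle(SyntheticConfig(seed=7, age_groups=groups))


@pytest.fixture()
def base_scenario():
    return TaxScenario()
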