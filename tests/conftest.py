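import pytest

from expotra import (
    CampaignSpec,
    default_baseline_config,
    default_config,
    generate_campaign,
    known_answer_campaign,
)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def baseline_config():
    return default_baseline_config()


@pytest.fixture(scope="session")
def bundle():
    return known_answer_campaign()


@pytest.fixture(scope="session")
def small_campaign():
    """Default-sized (430-sample) campaign, fixed seed."""
    return generate_campaign(CampaignSpec(seed=12345))


@pytest.fixture(scope="session")
def large_campaign():
    """10,000-sample campaign with median-unbiased noise, fixed seed."""
    return generate_campaign(CampaignSpec(seed=20177, n_measurements=10_000))
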