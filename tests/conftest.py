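import pytest
from hypothesis import HealthCheck, settings

import ergolever as el

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return el.datasets.load_design()


@pytest.fixture(scope="session")
def features_long():
    return el.datasets.load_emg_features()


@pytest.fixture(scope="session")
def mvc_table(features_long):
    return el.datasets.mvc_wide(features_long)


@pytest.fixture(scope="session")
def effects(design, mvc_table):
    return el.main_effects(design, mvc_table)
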