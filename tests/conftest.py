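import pytest
from hypothesis import HealthCheck, settings

import sultpbpk as sp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def apap_profile():
    return sp.apap()


@pytest.fixture(scope="session")
def physiology():
    return sp.default_physiology()


@pytest.fixture(scope="session")
def clearance_model(apap_profile, physiology):
    return sp.ClearanceModel(apap_profile, physiology)


@pytest.fixture(scope="session")
def pbpk_model(apap_profile, physiology):
    return sp.PBPKModel(apap_profile, physiology)


@pytest.fixture(scope="session")
def ontogeny_library():
    return sp.builtin_ontogeny_library()
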