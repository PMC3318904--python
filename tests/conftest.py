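import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blosum62():
    from psse import load_matrix

    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def gaps():
    from psse import GapPenalties

    return GapPenalties(open=10, extend=2)
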