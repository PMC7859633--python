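import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    from strokequant import DEFAULT_LABEL_SCHEME

    return DEFAULT_LABEL_SCHEME


@pytest.fixture(scope="session")
def phantom_bundle():
    """One default phantom at 1 mm spacing, shared across tests."""
    from strokequant import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec(spacing=1.0))
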