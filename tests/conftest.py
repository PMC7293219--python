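import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def variant_pool():
    """The full 1088-strand promoter-variant pool (seeded, built once)."""
    from doriskit import build_variant_pool

    return build_variant_pool(seed=11)


@pytest.fixture(scope="session")
def three_file_db():
    """A three-file database analogous to files A, B, C."""
    from doriskit import make_fixture_database

    return make_fixture_database(
        n_files=3, strands_per_file=2, L=4, seed=5, copies_per_strand=200
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
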