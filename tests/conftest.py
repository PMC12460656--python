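import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def wake_tep():
    """A default 8-component wakefulness TMS-evoked trial set."""
    import dreamcomplexity as dc

    return dc.gen_tep(dc.wake_tep_spec(8, 40, seed=5), 8, 500.0, seed=5)


@pytest.fixture(scope="session")
def small_epochs():
    """A small eyes-open spontaneous EEG recording (4 ch, 20 s)."""
    import dreamcomplexity as dc

    profile = dc.default_profiles()["wake_eo"]
    return dc.gen_spontaneous(profile, 4, 20.0, 250.0, seed=11)
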