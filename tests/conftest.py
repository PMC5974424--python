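import pytest

from imksurv import PARAMETER_PRESETS, PHASE_STATS


@pytest.fixture(scope="session")
def plateau():
    """CHO-K1 plateau-phase baseline parameters (the reference state)."""
    return PARAMETER_PRESETS["cho-k1-plateau"]


@pytest.fixture(scope="session")
def logphase():
    """CHO-K1 logarithmic-growth-phase parameters."""
    return PARAMETER_PRESETS["cho-k1-log"]


@pytest.fixture(scope="session")
def plateau_stats():
    return PHASE_STATS["cho-k1-plateau"]


@pytest.fixture(scope="session")
def log_stats():
    return PHASE_STATS["cho-k1-log"]
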