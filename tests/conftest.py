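import numpy as np
import pytest

from screamkit.features import extract_all
from screamkit.synth import StudyConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One fully rendered default synthetic study (the study conditions)."""
    return simulate_study(StudyConfig(seed=11))


@pytest.fixture(scope="session")
def default_tables(default_study):
    """Call- and bout-level feature tables extracted from the default study."""
    call, bout = extract_all(default_study.clips, default_study.annotations)
    return call, bout


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
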