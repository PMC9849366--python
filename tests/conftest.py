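import numpy as np
import pytest

from foldbind.pipeline import make_fixture_study, run_study
from foldbind.pipeline import StudyConfig


@pytest.fixture(scope="session")
def fixture_study(tmp_path_factory):
    """The synthetic five-variant study, generated once per session."""
    root = tmp_path_factory.mktemp("study")
    config_path = make_fixture_study(root, seed=1)
    report = run_study(StudyConfig.from_yaml(config_path))
    return config_path, report


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
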