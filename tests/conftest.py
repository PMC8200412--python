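import numpy as np
import pytest

from crossomics.simulate import GeneratorConfig, generate_trial, worked_fixture


@pytest.fixture(scope="session")
def fixture_trial():
    """The tiny hand-built 6-subject trial."""
    return worked_fixture()


@pytest.fixture(scope="session")
def default_trial():
    """One default synthetic trial (20 subjects, no planted effects)."""
    ds, truth = generate_trial(GeneratorConfig(seed=42))
    return ds, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20210531)
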