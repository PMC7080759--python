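import pytest

from spiroprotect.synthetic_experiment import (
    ExperimentDesign,
    default_params,
    generate_all,
)


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign(seed=123)


@pytest.fixture(scope="session")
def tables(design, params):
    """One full synthetic experiment at the default (study-scale) design."""
    return generate_all(design, params, seed=123)
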