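import pytest

from glaucoma_cea import Strategy, default_parameter_set


@pytest.fixture(scope="session")
def params():
    """Packaged default parameter set (deterministic)."""
    return default_parameter_set()


@pytest.fixture(scope="session")
def usual_care_40():
    return Strategy.usual_care("40-75")


@pytest.fixture(scope="session")
def annual_f2f_universal_40():
    return Strategy("40-75", "universal", "f2f", "annual")
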