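import warnings

import pytest

from acmodes import ModelParameters, build_default_network


@pytest.fixture(scope="session")
def params():
    """Published default parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def def_top(params):
    """Serial five-area (DEF) topology."""
    return build_default_network(params)


@pytest.fixture(autouse=True)
def _quiet_short_soi_warning():
    # several experiments legitimately probe SOIs below the decay-assumption
    # threshold; the warning itself is tested explicitly once
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="SOI .* is below", category=UserWarning
        )
        yield
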