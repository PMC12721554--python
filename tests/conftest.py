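import math

import pytest

from txswitch.io import preset_config, spec_from_config


@pytest.fixture(scope="session")
def fig1_spec():
    return spec_from_config(preset_config("fig1"))


@pytest.fixture(scope="session")
def fig2_spec():
    return spec_from_config(preset_config("fig2_hill4"))


@pytest.fixture(scope="session")
def fig3_spec():
    return spec_from_config(preset_config("fig3_hill50"))


@pytest.fixture(scope="session")
def fig4_spec():
    return spec_from_config(preset_config("fig4_nfl"))


@pytest.fixture(scope="session")
def fig5_spec():
    return spec_from_config(preset_config("fig5_multitarget"))


def telegraph_fano(alpha, beta, kon, koff):
    """Classical two-state (telegraph) promoter Fano factor."""
    return 1.0 + alpha * koff / ((kon + koff) * (kon + koff + beta))
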