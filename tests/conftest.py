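import numpy as np
import pytest

import mdmc


@pytest.fixture(scope="session")
def vt_mdmc():
    """Published base-variant parameter set of the visual-tactile task."""
    return mdmc.load_fixture("vt_mdmc")


@pytest.fixture(scope="session")
def vt_fnmdmc():
    """Published faster-neutral parameter set of the visual-tactile task."""
    return mdmc.load_fixture("vt_fnmdmc")


@pytest.fixture(scope="session")
def va_mdmc():
    return mdmc.load_fixture("va_mdmc")


@pytest.fixture(scope="session")
def nine():
    return mdmc.nine_conditions("tactile")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def vt_table(vt_mdmc):
    """Moderately sized simulated dataset at the published parameters."""
    return mdmc.simulate_experiment(
        vt_mdmc, mdmc.nine_conditions("tactile"), 4000, "mdmc", 101
    )
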