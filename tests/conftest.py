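import pytest

from multiscreen.chem_io import TargetConfig
from multiscreen.synthdata import SimSpec, make_full_study


@pytest.fixture(scope="session")
def small_targets():
    """A three-target panel covering all three model modes."""
    return {
        "T-COMB": TargetConfig("T-COMB", activity_threshold=6.0),
        "T-QSAR": TargetConfig("T-QSAR", activity_threshold=5.0, has_docking=False),
        "T-DOCK": TargetConfig("T-DOCK", has_qsar=False),
    }


@pytest.fixture(scope="session")
def small_spec():
    return SimSpec(
        n_active=40, n_inactive=40, n_descriptors=10, separation=6.0,
        seed=7, n_library=60, n_planted=15,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec, small_targets):
    return make_full_study(small_spec, small_targets)
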