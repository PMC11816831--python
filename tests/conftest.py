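import pytest

from sdwave import default_layout, simulate_cohort


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def unit_bundle():
    """One small simulated animal (2 h, 2 ECoG + 2 IOS SDs, 1 LSCI SD)."""
    bundle, roster = simulate_cohort("unit_test", 1)
    return bundle, roster
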