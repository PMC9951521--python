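import numpy as np
import pytest

from purepremium.copulas import CopulaSpec
from purepremium.synthetic import SyntheticConfig, simulate_panel


@pytest.fixture(scope="session")
def default_panel():
    """Default-calibration panel, 7 years."""
    return simulate_panel(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def recovery_panel():
    """Uniform-exposure panel long enough for estimation checks."""
    cfg = SyntheticConfig(
        seed=7,
        years=tuple(range(2000, 2015)),
        base_exposed=np.full(56, 3000.0),
    )
    return cfg, simulate_panel(cfg)


@pytest.fixture(scope="session")
def frank_spec():
    return CopulaSpec("frank", 5.0)
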