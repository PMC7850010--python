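import numpy as np
import pytest

from bildsim import ListenerProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_listener():
    """Typical listener: 2-dB slope, 2% lapses, 6-dB true BILD."""
    return ListenerProfile(
        age_years=10.0,
        group="child",
        mu_m0t0=-10.0,
        bild_true=6.0,
        mu_quiet=-35.0,
    )


@pytest.fixture
def steep_listener():
    """Near-deterministic listener used for unbiasedness checks."""
    return ListenerProfile(
        age_years=30.0,
        group="adult",
        mu_m0t0=-10.0,
        bild_true=6.0,
        mu_quiet=-35.0,
        slope=0.2,
        lapse_rate=0.0,
    )
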