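import numpy as np
import pytest

from greenshift import make_world


@pytest.fixture(scope="session")
def world():
    """A rugged, mildly noisy synthetic study region."""
    return make_world(n_rows=40, n_cols=40, seed=7)


@pytest.fixture(scope="session")
def flat_world():
    """A noise-free, relief-free world: climate varies with latitude only."""
    return make_world(n_rows=40, n_cols=40, relief=0.0, noise_sd=0.0, seed=11)


def random_monthly_profile(rng):
    """A plausible subarctic monthly temperature series for oracle checks."""
    annual = rng.uniform(-12.0, 10.0)
    amplitude = rng.uniform(5.0, 18.0)
    months = np.arange(1, 13)
    cycle = amplitude * np.cos(2 * np.pi * (months - 7) / 12.0)
    return annual + cycle + rng.normal(0.0, 1.0, size=12)
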