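import numpy as np
import pytest

from nucleokin.datatypes import FrapCurve


def make_frap_curve(y0=0.05, a_fast=0.68, tau_fast=0.8, a_slow=0.03, tau_slow=8.0,
                    dt=0.2, duration=20.0, noise_sd=0.0, rng=None, cell_id="c0",
                    normalized=True, gain=1.0):
    """Closed-form two-component recovery on the standard grid, optionally noisy."""
    t_post = np.arange(0.0, duration + dt / 2, dt)
    times = np.concatenate([[-dt], t_post])
    is_pre = np.zeros(times.size, dtype=bool)
    is_pre[0] = True
    values = y0 + a_fast * (1 - np.exp(-t_post / tau_fast)) \
        + a_slow * (1 - np.exp(-t_post / tau_slow))
    values = np.concatenate([[1.0], values])
    if noise_sd > 0:
        values = values + (rng or np.random.default_rng(0)).normal(0, noise_sd, values.size)
    return FrapCurve(cell_id, times, values * gain, is_pre, normalized=(gain == 1.0 and normalized))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
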