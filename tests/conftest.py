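import numpy as np
import pytest

import eidesign as ed
from eidesign.experiment import ROLE_SPIKES, ROLE_STIMULUS, _simulate_rate, stream
from eidesign.spikes import Dataset, sample_spikes


@pytest.fixture(scope="session")
def truth():
    return ed.true_params()


@pytest.fixture(scope="session")
def baseline(truth):
    """Resting state of the generating network at zero input."""
    return ed.find_equilibrium(truth, 0.0).as_array()


@pytest.fixture(scope="session")
def bounds():
    return ed.default_bounds()


def make_random_dataset(truth, baseline, M, seed, dt=0.01, N=5,
                        f_base=10.0 / 3.0, T=3.0, A_max=120.0) -> Dataset:
    """Random-stimulus dataset of M spike trains from the generating network."""
    sb = ed.StimulusBounds(A_max=A_max)
    ds = Dataset()
    for m in range(M):
        stim = ed.random_stimulus(sb, N, f_base, T, stream(seed, ROLE_STIMULUS, m))
        times, rate = _simulate_rate(truth, stim, dt, baseline)
        ds.append(stim, sample_spikes(rate, T, stream(seed, ROLE_SPIKES, m), times))
    return ds


def random_bounded_params(rng, truth):
    """Parameter draw uniform in the estimation box, keeping the fixed gains."""
    lo, hi = ed.default_bounds().lower, ed.default_bounds().upper
    # keep betas away from 0 so time scales stay well-defined
    th = rng.uniform(lo, hi)
    th[0] = rng.uniform(20.0, 80.0)
    th[1] = rng.uniform(10.0, 60.0)
    return truth.with_theta(th)
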