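"""Default study configuration: ground truth, bounds, gain and stimulus constants.

These are the generating values used throughout the package's simulated
experiments: the excitatory unit fires up to 100 spikes/s with soft
threshold 70 and slope 0.04, the inhibitory unit up to 50 spikes/s with
threshold 35; the true network has time constants 20 ms (excitatory) and
40 ms (inhibitory).  Stimuli are 3-s sums of N = 5 harmonics of a 10/3 Hz
base frequency with amplitudes bounded by 120.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import GainParams, NetworkParams

DEFAULT_GAIN_E = GainParams(Gamma=100.0, a=0.04, h=70.0)
DEFAULT_GAIN_I = GainParams(Gamma=50.0, a=0.04, h=35.0)

TRUE_THETA = np.array([50.0, 25.0, 1.0, 0.7, 1.2, 2.0, 0.7, 0.4])
THETA_LOWER = np.zeros(8)
THETA_UPPER = np.array([100.0, 100.0, 2.0, 2.0, 3.0, 3.0, 3.0, 3.0])


def true_params() -> NetworkParams:
    """Ground-truth network used as the generating model in simulations."""
    return NetworkParams.from_theta(TRUE_THETA, DEFAULT_GAIN_E, DEFAULT_GAIN_I)


def default_bounds():
    """Estimation box: betas in [0, 100], input weights in [0, 2], recurrent in [0, 3]."""
    from .estimation import ParameterBounds

    return ParameterBounds(THETA_LOWER.copy(), THETA_UPPER.copy())


@dataclass(frozen=True)
class StimulusConfig:
    """Stimulus family and integration settings shared across an experiment."""

    N: int = 5
    f_base: float = 10.0 / 3.0
    T: float = 3.0
    A_max: float = 120.0
    dt: float = 1e-3
    # initial condition for each presentation: equilibrium of the autonomous
    # system at I=0 (pre-stimulus baseline); set False to use I(0) instead
    equilibrium_at_zero_input: bool = True


def default_stimulus_config() -> StimulusConfig:
    return StimulusConfig()
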