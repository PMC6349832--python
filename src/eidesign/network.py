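"""Two-unit excitatory-inhibitory rate network: dynamics, simulation, equilibria.

The model is the classic firing-rate network restricted to one excitatory (e)
and one inhibitory (i) unit.  Each unit carries a membrane-potential-like
state V with inverse time constant beta, and communicates through a logistic
gain function g(V) = Gamma / (1 + exp(-a (V - h))):

    dV_e/dt = beta_e * (-V_e + w_ee g_e(V_e) - w_ei g_i(V_i) + w_e I)
    dV_i/dt = beta_i * (-V_i + w_ie g_e(V_e) - w_ii g_i(V_i) + w_i I)

All weights are nonnegative; the sign of inhibition is explicit in the
equations.  The observable is the excitatory rate r_e = g_e(V_e), which
drives an inhomogeneous Poisson spike process (see :mod:`eidesign.spikes`).
Units: time in seconds, rates in spikes/s, so beta_e = 50 1/s means a 20 ms
membrane time constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import root
from scipy.special import expit


class IntegrationError(RuntimeError):
    """Raised when a fixed-step integration produces a non-finite state."""

    def __init__(self, message: str, t: float | None = None, block: str | None = None):
        super().__init__(message)
        self.t = t
        self.block = block


@dataclass(frozen=True)
class GainParams:
    """Logistic gain-function constants of one unit.

    Gamma : maximum firing rate (spikes/s), > 0
    a     : slope (1/voltage-unit), > 0
    h     : soft threshold (voltage-units); g(h) = Gamma/2
    """

    Gamma: float
    a: float
    h: float

    def __post_init__(self):
        if not (self.Gamma > 0 and self.a > 0):
            raise ValueError("Gamma and a must be positive")


def gain(V, gp: GainParams, order: int = 0):
    """Logistic gain g(V) = Gamma/(1+exp(-a(V-h))) or its V-derivative.

    order 0 returns the rate, order 1 and 2 the exact first and second
    derivatives.  Accepts scalars or arrays.
    """
    s = expit(gp.a * (np.asarray(V, dtype=float) - gp.h))
    if order == 0:
        out = gp.Gamma * s
    elif order == 1:
        out = gp.Gamma * gp.a * s * (1.0 - s)
    elif order == 2:
        out = gp.Gamma * gp.a**2 * s * (1.0 - s) * (1.0 - 2.0 * s)
    else:
        raise ValueError("order must be 0, 1 or 2")
    return out if out.ndim else float(out)


# parameter names in the canonical theta ordering
THETA_NAMES = ("beta_e", "beta_i", "w_e", "w_i", "w_ee", "w_ei", "w_ie", "w_ii")


@dataclass(frozen=True)
class NetworkParams:
    """The eight estimated network parameters plus fixed gain constants.

    The theta-vector view is exactly
    [beta_e, beta_i, w_e, w_i, w_ee, w_ei, w_ie, w_ii]; all eight entries are
    nonnegative (inhibition signs are written into the equations).
    """

    beta_e: float
    beta_i: float
    w_e: float
    w_i: float
    w_ee: float
    w_ei: float
    w_ie: float
    w_ii: float
    gain_e: GainParams = field(default=GainParams(100.0, 0.04, 70.0))
    gain_i: GainParams = field(default=GainParams(50.0, 0.04, 35.0))

    def __post_init__(self):
        th = self.theta
        if not np.all(np.isfinite(th)):
            raise ValueError("network parameters must be finite")
        if np.any(th < 0):
            raise ValueError("network parameters must be nonnegative")

    @property
    def theta(self) -> np.ndarray:
        return np.array(
            [self.beta_e, self.beta_i, self.w_e, self.w_i,
             self.w_ee, self.w_ei, self.w_ie, self.w_ii]
        )

    @classmethod
    def from_theta(cls, theta, gain_e: GainParams | None = None,
                   gain_i: GainParams | None = None) -> "NetworkParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (8,):
            raise ValueError("theta must be an 8-vector")
        kwargs = dict(zip(THETA_NAMES, theta.tolist()))
        if gain_e is not None:
            kwargs["gain_e"] = gain_e
        if gain_i is not None:
            kwargs["gain_i"] = gain_i
        return cls(**kwargs)

    def with_theta(self, theta) -> "NetworkParams":
        return NetworkParams.from_theta(theta, self.gain_e, self.gain_i)

    def replace(self, **kwargs) -> "NetworkParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class NetworkState:
    """Membrane-potential-like states of the two units."""

    V_e: float
    V_i: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V_e, self.V_i])


@dataclass
class Trajectory:
    """Time courses of the network state and the excitatory rate on a uniform grid."""

    times: np.ndarray
    V_e: np.ndarray
    V_i: np.ndarray
    r_e: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "V_e": self.V_e, "V_i": self.V_i, "r_e": self.r_e}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def vector_field(state, I: float, p: NetworkParams) -> np.ndarray:
    """Right-hand side (dV_e/dt, dV_i/dt) at one state and stimulus value."""
    V_e, V_i = (state.V_e, state.V_i) if isinstance(state, NetworkState) else state
    ge = gain(V_e, p.gain_e)
    gi = gain(V_i, p.gain_i)
    dVe = p.beta_e * (-V_e + p.w_ee * ge - p.w_ei * gi + p.w_e * I)
    dVi = p.beta_i * (-V_i + p.w_ie * ge - p.w_ii * gi + p.w_i * I)
    return np.array([dVe, dVi])


def _rk4_callable(p: NetworkParams, stimulus: Callable, T: float, dt: float,
                  v0: np.ndarray) -> Trajectory:
    n_steps = int(round(T / dt))
    times = np.arange(n_steps + 1) * dt
    V = np.empty((n_steps + 1, 2))
    V[0] = v0
    y = v0.astype(float).copy()
    for j in range(n_steps):
        t = j * dt
        k1 = vector_field(y, stimulus(t), p)
        I_half = stimulus(t + 0.5 * dt)
        k2 = vector_field(y + 0.5 * dt * k1, I_half, p)
        k3 = vector_field(y + 0.5 * dt * k2, I_half, p)
        k4 = vector_field(y + dt * k3, stimulus(t + dt), p)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"non-finite state at t={times[j + 1]:.6g} s", t=float(times[j + 1]),
                block="state")
        V[j + 1] = y
    r_e = gain(V[:, 0], p.gain_e)
    return Trajectory(times, V[:, 0], V[:, 1], r_e)


def simulate(p: NetworkParams, stimulus: Callable, T: float, dt: float = 1e-3,
             v0=None) -> Trajectory:
    """Fixed-step RK4 integration of the network under a time-varying stimulus.

    `stimulus` is any callable t -> I(t) (a :class:`FourierStimulus` works).
    The grid is uniform with step `dt`; identical inputs give bit-identical
    output.  If `v0` is None the integration starts from the equilibrium of
    the autonomous system (I = 0), the pre-stimulus baseline.
    """
    if not (T > 0 and 0 < dt <= T):
        raise ValueError("require T > 0 and 0 < dt <= T")
    if v0 is None:
        eq = find_equilibrium(p, 0.0)
        v0 = eq.as_array()
    elif isinstance(v0, NetworkState):
        v0 = v0.as_array()
    else:
        v0 = np.asarray(v0, dtype=float)
    # Fourier stimuli go through the compiled augmented integrator so that the
    # plain-state path and the sensitivity path share one scheme exactly.
    from .stimulus import FourierStimulus

    if isinstance(stimulus, FourierStimulus):
        from .sensitivity import solve_sensitivities

        traj, _ = solve_sensitivities(p, stimulus, T, dt, which="state", v0=v0)
        return traj
    return _rk4_callable(p, stimulus, T, dt, v0)


def find_equilibrium(p: NetworkParams, I_const: float = 0.0,
                     max_iter: int = 500, tol: float = 1e-8) -> NetworkState:
    """Equilibrium state under a constant stimulus.

    Damped fixed-point iteration on V = W_signed g(V) + w I followed by a
    root polish; the returned state satisfies ||vector_field|| < `tol`.
    """
    V = np.zeros(2)
    damp = 0.5
    for _ in range(max_iter):
        ge = gain(V[0], p.gain_e)
        gi = gain(V[1], p.gain_i)
        target = np.array(
            [p.w_ee * ge - p.w_ei * gi + p.w_e * I_const,
             p.w_ie * ge - p.w_ii * gi + p.w_i * I_const]
        )
        V_new = (1 - damp) * V + damp * target
        if not np.all(np.isfinite(V_new)):
            raise IntegrationError("fixed-point iteration diverged", block="equilibrium")
        if np.max(np.abs(V_new - V)) < 1e-10:
            V = V_new
            break
        V = V_new
    sol = root(lambda v: vector_field(v, I_const, p), V, tol=1e-13)
    V = sol.x
    if np.linalg.norm(vector_field(V, I_const, p)) >= tol:
        raise IntegrationError(
            "equilibrium search did not converge (pathological parameter set?)",
            block="equilibrium")
    return NetworkState(float(V[0]), float(V[1]))
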