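"""Fourier-series stimuli: evaluation, derivatives, random controls.

A stimulus is I(t) = sum_n A_n cos(omega_n t + phi_n) with harmonic
frequencies omega_n = 2 pi n f_base.  Its free parameters form the vector
x = [A_1..A_N, phi_1..phi_N]; amplitudes are bounded in [0, A_max] while
phases vary freely during optimization and are wrapped to [-pi, pi) only
for storage and reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def wrap_phase(phi):
    """Wrap phases to [-pi, pi); leaves the stimulus waveform unchanged."""
    return np.mod(np.asarray(phi, dtype=float) + np.pi, 2 * np.pi) - np.pi


@dataclass(frozen=True)
class StimulusBounds:
    """Amplitude box for stimulus optimization; phases are unbounded."""

    A_max: float = 120.0
    A_min: float = 0.0
    bound_phases: bool = False

    def __post_init__(self):
        if not self.A_min < self.A_max:
            raise ValueError("A_min must be < A_max")


@dataclass(frozen=True)
class FourierStimulus:
    """Sum of N phased cosines on harmonics of a base frequency."""

    A: np.ndarray
    phi: np.ndarray
    f_base: float = 10.0 / 3.0
    T: float = 3.0

    def __post_init__(self):
        object.__setattr__(self, "A", np.atleast_1d(np.asarray(self.A, dtype=float)))
        object.__setattr__(self, "phi", np.atleast_1d(np.asarray(self.phi, dtype=float)))
        if self.A.shape != self.phi.shape or self.A.ndim != 1:
            raise ValueError("A and phi must be 1-D arrays of equal length")
        if np.any(self.A < 0):
            raise ValueError("amplitudes must be nonnegative")

    @property
    def N(self) -> int:
        return self.A.size

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies 2 pi n f_base, n = 1..N (rad/s)."""
        return 2 * np.pi * self.f_base * np.arange(1, self.N + 1)

    @property
    def x(self) -> np.ndarray:
        """Flattened parameter vector [A_1..A_N, phi_1..phi_N]."""
        return np.concatenate([self.A, self.phi])

    @classmethod
    def from_x(cls, x, f_base: float = 10.0 / 3.0, T: float = 3.0) -> "FourierStimulus":
        x = np.asarray(x, dtype=float)
        if x.size % 2:
            raise ValueError("x must have even length 2N")
        N = x.size // 2
        return cls(A=x[:N], phi=x[N:], f_base=f_base, T=T)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        vals = np.sum(self.A * np.cos(np.multiply.outer(t, self.omega) + self.phi), axis=-1)
        return vals if vals.ndim else float(vals)

    def derivs(self, t):
        """2N-vector of dI/dx at time t: cos(...) for amplitudes, -A sin(...) for phases."""
        t = np.asarray(t, dtype=float)
        arg = np.multiply.outer(t, self.omega) + self.phi
        dA = np.cos(arg)
        dphi = -self.A * np.sin(arg)
        return np.concatenate([dA, dphi], axis=-1)

    def wrapped(self) -> "FourierStimulus":
        return FourierStimulus(self.A, wrap_phase(self.phi), self.f_base, self.T)

    def to_dict(self) -> dict:
        return {"A": self.A.tolist(), "phi": self.phi.tolist(),
                "f_base": self.f_base, "T": self.T}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "FourierStimulus":
        return cls(np.asarray(d["A"]), np.asarray(d["phi"]), d["f_base"], d["T"])

    def waveform_frame(self, dt: float = 1e-3) -> pd.DataFrame:
        t = np.arange(int(round(self.T / dt)) + 1) * dt
        return pd.DataFrame({"time": t, "I": self(t)})


def eval_stimulus(stim: FourierStimulus, t):
    """Functional alias for stimulus evaluation."""
    return stim(t)


def stimulus_derivs(stim: FourierStimulus, t):
    """Functional alias for the stimulus-parameter derivative vector."""
    return stim.derivs(t)


def random_stimulus(bounds: StimulusBounds, N: int = 5, f_base: float = 10.0 / 3.0,
                    T: float = 3.0, rng: np.random.Generator | None = None
                    ) -> FourierStimulus:
    """Nonadaptive control stimulus: A_n ~ U[A_min, A_max], phi_n ~ U[-pi, pi)."""
    if rng is None:
        raise ValueError("a seeded rng is required for reproducibility")
    A = rng.uniform(bounds.A_min, bounds.A_max, size=N)
    phi = rng.uniform(-np.pi, np.pi, size=N)
    return FourierStimulus(A, phi, f_base, T)


@dataclass(frozen=True)
class square_wave:
    """Square-pulse demo stimulus: `amplitude` for t in [t_on, t_off), else 0."""

    amplitude: float = 60.0
    t_on: float = 0.5
    t_off: float = 2.5

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where((t >= self.t_on) & (t < self.t_off), self.amplitude, 0.0)
        return out if out.ndim else float(out)
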