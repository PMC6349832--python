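"""Inhomogeneous-Poisson spike trains, their log-likelihood and its gradient.

Spikes are generated by Ogata thinning against the maximum of the rate
trajectory, which is exact for a bounded intensity.  The log-likelihood of a
dataset of (stimulus, spike train) pairs under network parameters theta is

    l(theta) = sum_m [ -int_0^T r_e^{(m)}(t) dt + sum_k ln r_e^{(m)}(t_k) ]

with the integral taken by the trapezoid rule on the simulation grid and the
rate at spike times by linear interpolation.  The analytic gradient swaps
r_e for its parameter sensitivities (from :mod:`eidesign.sensitivity`).
A rate floor of 1e-9 spikes/s inside ln() and 1/() guards round-off only:
the logistic gain is strictly positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .network import NetworkParams, gain
from .sensitivity import _integrate_batch
from .stimulus import FourierStimulus

RATE_FLOOR = 1e-9


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times in an observation window [0, T]."""

    times: np.ndarray
    T: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] > self.T):
            raise ValueError("spike times must be strictly increasing within [0, T]")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class Dataset:
    """Accumulated (stimulus, spike train) pairs; responses are independent."""

    pairs: list[tuple[FourierStimulus, SpikeTrain]] = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.pairs)

    def append(self, stim: FourierStimulus, train: SpikeTrain) -> None:
        self.pairs.append((stim, train))

    def __iter__(self):
        return iter(self.pairs)

    def __add__(self, other: "Dataset") -> "Dataset":
        return Dataset(self.pairs + other.pairs)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for stim, train in self.pairs:
                rec = {"stimulus": stim.to_dict(), "spikes": train.times.tolist()}
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "Dataset":
        ds = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                stim = FourierStimulus.from_dict(rec["stimulus"])
                ds.append(stim, SpikeTrain(np.asarray(rec["spikes"]), stim.T))
        return ds


def sample_spikes(r: np.ndarray, T: float, rng: np.random.Generator,
                  times: np.ndarray | None = None) -> SpikeTrain:
    """Draw one spike train from an inhomogeneous Poisson process.

    `r` is the rate (spikes/s) on a uniform grid over [0, T]; the intensity
    between grid points is its linear interpolation.  Thinning against the
    bound max(r): candidate events arrive at the constant bound rate and are
    accepted with probability r(t)/bound.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("rate must be nonnegative")
    if times is None:
        times = np.linspace(0.0, T, r.size)
    r_max = float(np.max(r))
    if r_max <= 0:
        return SpikeTrain(np.empty(0), T)
    spikes = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / r_max)
        if t > T:
            break
        if rng.uniform() * r_max < np.interp(t, times, r):
            spikes.append(t)
    return SpikeTrain(np.asarray(spikes), T)


def _check_uniform(data: Dataset):
    stim0 = data.pairs[0][0]
    for stim, _ in data.pairs:
        if (stim.N != stim0.N or stim.f_base != stim0.f_base or stim.T != stim0.T):
            raise ValueError("all stimuli in a dataset must share N, f_base and T")
    return stim0


def log_likelihood_and_gradient(data: Dataset, p: NetworkParams, dt: float = 1e-3,
                                with_grad: bool = True,
                                v0: np.ndarray | None = None):
    """Log-likelihood of the dataset and (optionally) its 8-vector gradient.

    All stimuli are simulated as one batch on a shared grid.  Additive over
    the pairs of the dataset.  `v0` is the pre-stimulus baseline state of the
    preparation; passing it (rather than the default, the equilibrium of the
    candidate parameters) keeps the analytic gradient exactly consistent with
    the objective, since the sensitivities start at zero.
    """
    if data.M == 0:
        raise ValueError("dataset is empty")
    stim0 = _check_uniform(data)
    A = np.stack([s.A for s, _ in data.pairs])
    phi = np.stack([s.phi for s, _ in data.pairs])
    which = "theta" if with_grad else "state"
    res = _integrate_batch(p, A, phi, stim0.f_base, stim0.T, dt, which, v0=v0)
    times = res["times"]
    Ve = res["V"][:, :, 0]                      # (nt, M)
    r = np.maximum(gain(Ve, p.gain_e), RATE_FLOOR)
    ll = -np.trapezoid(r, times, axis=0).sum()
    if with_grad:
        g1 = gain(Ve, p.gain_e, order=1)        # (nt, M)
        dre = g1[:, :, None] * res["dv_dtheta"][:, :, 0, :]   # (nt, M, 8)
        grad = -np.trapezoid(dre, times, axis=0).sum(axis=0)
    for m, (_, train) in enumerate(data.pairs):
        if len(train) == 0:
            continue
        r_sp = np.maximum(np.interp(train.times, times, r[:, m]), RATE_FLOOR)
        ll += np.log(r_sp).sum()
        if with_grad:
            for k in range(8):
                d_sp = np.interp(train.times, times, dre[:, m, k])
                grad[k] += (d_sp / r_sp).sum()
    if with_grad:
        return float(ll), grad
    return float(ll)


def log_likelihood(data: Dataset, p: NetworkParams, dt: float = 1e-3,
                   v0: np.ndarray | None = None) -> float:
    """Poisson spike-train log-likelihood of the accumulated dataset."""
    return log_likelihood_and_gradient(data, p, dt, with_grad=False, v0=v0)


def log_likelihood_gradient(data: Dataset, p: NetworkParams, dt: float = 1e-3,
                            v0: np.ndarray | None = None) -> np.ndarray:
    """Analytic gradient of the log-likelihood with respect to theta."""
    return log_likelihood_and_gradient(data, p, dt, with_grad=True, v0=v0)[1]
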