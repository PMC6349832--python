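"""Fisher-information utilities and A-optimal stimulus design.

For the Poisson-observed excitatory rate, the time-integrated Fisher
information about parameter theta_k carried by a stimulus x is

    U_k(x, theta) = int_0^T (1/r_e) (dr_e/dtheta_k)^2 dt

and the A-optimal (trace) utility is the sum over the eight parameters.
Stimuli are designed one parameter at a time by maximizing U_k with a
bounded quasi-Newton optimizer fed the analytic gradient

    dU_k/dx_l = int [ -(1/r_e^2)(dr_e/dx_l)(dr_e/dtheta_k)^2
                      + (2/r_e)(dr_e/dtheta_k)(d2r_e/dx_l dtheta_k) ] dt,

whose ingredients come from the forward sensitivity systems.  Optimizing
each U_k separately sidesteps the unit-dependence of the plain trace
criterion (a parameter with small units would otherwise dominate the sum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .network import NetworkParams
from .sensitivity import solve_sensitivities
from .spikes import RATE_FLOOR
from .stimulus import FourierStimulus, StimulusBounds

logger = logging.getLogger(__name__)


@dataclass
class UtilityEvaluation:
    """Per-parameter utilities U_k, their total, and optionally a gradient."""

    U_k: np.ndarray
    U: float
    grad_x: np.ndarray | None = None


def _rate_and_sens(x: FourierStimulus, p: NetworkParams, dt: float, which: str):
    traj, bundle = solve_sensitivities(p, x, x.T, dt, which=which)
    r = np.maximum(traj.r_e, RATE_FLOOR)
    return traj, bundle, r


def utility(x: FourierStimulus, p: NetworkParams, k: int | str = "total",
            dt: float = 1e-3) -> UtilityEvaluation:
    """Evaluate the per-parameter utilities (trapezoid on the simulation grid).

    `k` is a parameter index 0..7 or "total"; the returned object always
    carries all eight U_k and their sum.
    """
    traj, bundle, r = _rate_and_sens(x, p, dt, "theta")
    integrand = bundle.dre_dtheta**2 / r[:, None]
    U_k = np.trapezoid(integrand, traj.times, axis=0)
    return UtilityEvaluation(U_k=U_k, U=float(U_k.sum()))


def utility_and_gradient(x: FourierStimulus, p: NetworkParams,
                         k: int | str = "total", dt: float = 1e-3
                         ) -> UtilityEvaluation:
    """Utilities plus the analytic stimulus-gradient of the selected one."""
    traj, bundle, r = _rate_and_sens(x, p, dt, "all")
    dre_th = bundle.dre_dtheta                      # (nt, 8)
    dre_x = bundle.dre_dx                           # (nt, 2N)
    cross = bundle.d2re_dxdtheta                    # (nt, 2N, 8)
    U_all = np.trapezoid(dre_th**2 / r[:, None], traj.times, axis=0)
    if k == "total":
        integ = (-(dre_x[:, :, None] * dre_th[:, None, :] ** 2) / r[:, None, None] ** 2
                 + 2.0 * dre_th[:, None, :] * cross / r[:, None, None])
        grad = np.trapezoid(integ.sum(axis=2), traj.times, axis=0)
    else:
        integ = (-(dre_x * dre_th[:, None, k] ** 2) / r[:, None] ** 2
                 + 2.0 * dre_th[:, None, k] * cross[:, :, k] / r[:, None])
        grad = np.trapezoid(integ, traj.times, axis=0)
    return UtilityEvaluation(U_k=U_all, U=float(U_all.sum()), grad_x=grad)


def utility_gradient(x: FourierStimulus, p: NetworkParams, k: int | str = "total",
                     dt: float = 1e-3) -> np.ndarray:
    """2N-vector gradient of U_k (or the total utility) with respect to x."""
    return utility_and_gradient(x, p, k, dt).grad_x


def design_stimulus(p_hat: NetworkParams, k: int, bounds: StimulusBounds,
                    N: int = 5, f_base: float = 10.0 / 3.0, T: float = 3.0,
                    n_starts: int = 8, rng: np.random.Generator | None = None,
                    dt: float = 1e-3, maxiter: int = 200, gtol: float = 1e-6
                    ) -> tuple[FourierStimulus, float]:
    """Multistart bounded maximization of U_k over the stimulus parameters.

    Starts are drawn uniformly (A in [0, A_max], phi in [-pi, pi)); the best
    endpoint by achieved U_k wins, with exact ties broken by lowest start
    index.  Amplitudes are clipped to the box; phases vary freely.  Returns
    the designed stimulus (phases wrapped for reporting) and its U_k.
    """
    if rng is None:
        raise ValueError("a seeded rng is required")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    scale = np.concatenate([np.full(N, bounds.A_max), np.ones(N)])
    box = [(bounds.A_min / bounds.A_max, 1.0)] * N + [(None, None)] * N

    def neg_U(z):
        stim = FourierStimulus.from_x(z * scale, f_base, T)
        ev = utility_and_gradient(stim, p_hat, k, dt)
        return -ev.U_k[k], -ev.grad_x * scale

    best = None
    improved = False
    for s in range(n_starts):
        z0 = np.concatenate([
            rng.uniform(bounds.A_min / bounds.A_max, 1.0, size=N),
            rng.uniform(-np.pi, np.pi, size=N),
        ])
        try:
            sol = minimize(neg_U, z0, jac=True, method="L-BFGS-B", bounds=box,
                           options={"maxiter": maxiter, "gtol": gtol})
        except Exception as exc:  # keep long closed-loop runs alive
            logger.warning("design start %d failed: %s", s, exc)
            continue
        f0 = neg_U(z0)[0]
        if sol.fun < f0 - 1e-12:
            improved = True
        val = -sol.fun
        # strict > keeps the lowest start index on exact ties (determinism)
        if best is None or val > best[0]:
            best = (val, sol.x.copy(), s)
        logger.debug("design k=%d start=%d U=%.4g nit=%d", k, s, val, sol.nit)
    if best is None:
        raise RuntimeError("all design starts failed")
    if not improved:
        logger.warning("stimulus design for k=%d did not improve on any start", k)
    x_best = best[1] * scale
    x_best[:N] = np.clip(x_best[:N], bounds.A_min, bounds.A_max)
    stim = FourierStimulus.from_x(x_best, f_base, T).wrapped()
    return stim, float(best[0])
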