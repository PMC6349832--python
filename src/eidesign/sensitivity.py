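"""Forward sensitivity analysis of the E-I network.

The state equations are augmented with the ODE systems obeyed by the
derivatives of the state with respect to the eight network parameters
(dv/dtheta), the 2N stimulus parameters (dv/dx), and the second-order cross
derivatives (d2v/dx dtheta).  All requested blocks are integrated jointly
with the state by the same fixed-step RK4 scheme on one shared grid, so no
interpolation between state and sensitivities is ever needed.  Sensitivities
start at exactly zero (the initial state is an equilibrium, which does not
depend on the stimulus, and the parameter blocks are defined from a common
initial condition).

The per-parameter forcing terms of the first-order parameter block and of
the cross block are hard-coded for the canonical parameter ordering
[beta_e, beta_i, w_e, w_i, w_ee, w_ei, w_ie, w_ii]:

* beta rows force with the corresponding row of the braced vector field
  (-v + W g(v) + w I), respectively its x-derivative for the cross block;
* input-weight rows force with B e_unit I (respectively B e_unit dI/dx);
* connection-weight rows force with B (signed selector) [g_e, g_i]
  (respectively the same selector applied to G dv/dx).

The compiled kernel below is the package's computational core; everything
else (likelihood, Fisher utilities and their gradients) is a quadrature
over its output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import cos, exp, sin

import numpy as np
from numba import njit

from .network import GainParams, IntegrationError, NetworkParams, Trajectory, gain
from .stimulus import FourierStimulus

_WHICH = {
    "state": (0, 0, 0),
    "theta": (1, 0, 0),
    "x": (0, 1, 0),
    "theta+x": (1, 1, 0),
    "all": (1, 1, 1),
    "cross": (1, 1, 1),
}


@dataclass
class SensitivityBundle:
    """Time courses of state/rate sensitivities for one stimulus.

    Array layouts (time axis first): dv_dtheta (nt, 2, 8), dv_dx (nt, 2, 2N),
    d2v_dxdtheta (nt, 2, 2N, 8); rate blocks dre_dtheta (nt, 8),
    dre_dx (nt, 2N), d2re_dxdtheta (nt, 2N, 8).  Unrequested blocks are None.
    """

    dv_dtheta: np.ndarray | None = None
    dv_dx: np.ndarray | None = None
    d2v_dxdtheta: np.ndarray | None = None
    dre_dtheta: np.ndarray | None = field(default=None)
    dre_dx: np.ndarray | None = field(default=None)
    d2re_dxdtheta: np.ndarray | None = field(default=None)


@njit(cache=True)
def _rhs(y, dy, t, A, phi, omega, th, Ge, ae, he, Gi, ai, hi,
         wt, wx, wc, L, ox, oc):  # pragma: no cover - exercised via wrapper
    M = y.shape[0]
    N = omega.shape[0]
    be = th[0]; bi = th[1]; we = th[2]; wi = th[3]
    wee = th[4]; wei = th[5]; wie = th[6]; wii = th[7]
    dIdx = np.empty(L)
    braceSx0 = np.empty(L)
    braceSx1 = np.empty(L)
    for m in range(M):
        I = 0.0
        for n in range(N):
            I += A[m, n] * cos(omega[n] * t + phi[m, n])
        Ve = y[m, 0]; Vi = y[m, 1]
        se = 1.0 / (1.0 + exp(-ae * (Ve - he)))
        si = 1.0 / (1.0 + exp(-ai * (Vi - hi)))
        ge = Ge * se; gpe = Ge * ae * se * (1.0 - se)
        gppe = Ge * ae * ae * se * (1.0 - se) * (1.0 - 2.0 * se)
        gi = Gi * si; gpi = Gi * ai * si * (1.0 - si)
        gppi = Gi * ai * ai * si * (1.0 - si) * (1.0 - 2.0 * si)
        brace_e = -Ve + wee * ge - wei * gi + we * I
        brace_i = -Vi + wie * ge - wii * gi + wi * I
        dy[m, 0] = be * brace_e
        dy[m, 1] = bi * brace_i
        J00 = be * (-1.0 + wee * gpe); J01 = -be * wei * gpi
        J10 = bi * wie * gpe; J11 = bi * (-1.0 - wii * gpi)
        if wt == 1:
            for k in range(8):
                s0 = y[m, 2 + k]; s1 = y[m, 10 + k]
                d0 = J00 * s0 + J01 * s1
                d1 = J10 * s0 + J11 * s1
                if k == 0:
                    d0 += brace_e
                elif k == 1:
                    d1 += brace_i
                elif k == 2:
                    d0 += be * I
                elif k == 3:
                    d1 += bi * I
                elif k == 4:
                    d0 += be * ge
                elif k == 5:
                    d0 += -be * gi
                elif k == 6:
                    d1 += bi * ge
                else:
                    d1 += -bi * gi
                dy[m, 2 + k] = d0
                dy[m, 10 + k] = d1
        if wx == 1:
            for n in range(N):
                arg = omega[n] * t + phi[m, n]
                dIdx[n] = cos(arg)
                dIdx[N + n] = -A[m, n] * sin(arg)
            for l in range(L):
                sx0 = y[m, ox + l]; sx1 = y[m, ox + L + l]
                b0 = -sx0 + wee * gpe * sx0 - wei * gpi * sx1 + we * dIdx[l]
                b1 = -sx1 + wie * gpe * sx0 - wii * gpi * sx1 + wi * dIdx[l]
                braceSx0[l] = b0
                braceSx1[l] = b1
                dy[m, ox + l] = be * b0
                dy[m, ox + L + l] = bi * b1
        if wc == 1:
            BW00 = be * wee; BW01 = -be * wei
            BW10 = bi * wie; BW11 = -bi * wii
            for l in range(L):
                sx0 = y[m, ox + l]; sx1 = y[m, ox + L + l]
                for k in range(8):
                    c0 = y[m, oc + l * 8 + k]
                    c1 = y[m, oc + (L + l) * 8 + k]
                    q0 = gppe * y[m, 2 + k] * sx0
                    q1 = gppi * y[m, 10 + k] * sx1
                    d0 = J00 * c0 + J01 * c1 + BW00 * q0 + BW01 * q1
                    d1 = J10 * c0 + J11 * c1 + BW10 * q0 + BW11 * q1
                    if k == 0:
                        d0 += braceSx0[l]
                    elif k == 1:
                        d1 += braceSx1[l]
                    elif k == 2:
                        d0 += be * dIdx[l]
                    elif k == 3:
                        d1 += bi * dIdx[l]
                    elif k == 4:
                        d0 += be * gpe * sx0
                    elif k == 5:
                        d0 += -be * gpi * sx1
                    elif k == 6:
                        d1 += bi * gpe * sx0
                    else:
                        d1 += -bi * gpi * sx1
                    dy[m, oc + l * 8 + k] = d0
                    dy[m, oc + (L + l) * 8 + k] = d1


@njit(cache=True)
def _rk4(y0, out, n_steps, dt, A, phi, omega, th, Ge, ae, he, Gi, ai, hi,
         wt, wx, wc, L, ox, oc):  # pragma: no cover - exercised via wrapper
    M, D = y0.shape
    y = y0.copy()
    k1 = np.empty((M, D)); k2 = np.empty((M, D))
    k3 = np.empty((M, D)); k4 = np.empty((M, D))
    tmp = np.empty((M, D))
    out[0] = y
    for j in range(n_steps):
        t = j * dt
        _rhs(y, k1, t, A, phi, omega, th, Ge, ae, he, Gi, ai, hi,
             wt, wx, wc, L, ox, oc)
        for m in range(M):
            for d in range(D):
                tmp[m, d] = y[m, d] + 0.5 * dt * k1[m, d]
        _rhs(tmp, k2, t + 0.5 * dt, A, phi, omega, th, Ge, ae, he, Gi, ai, hi,
             wt, wx, wc, L, ox, oc)
        for m in range(M):
            for d in range(D):
                tmp[m, d] = y[m, d] + 0.5 * dt * k2[m, d]
        _rhs(tmp, k3, t + 0.5 * dt, A, phi, omega, th, Ge, ae, he, Gi, ai, hi,
             wt, wx, wc, L, ox, oc)
        for m in range(M):
            for d in range(D):
                tmp[m, d] = y[m, d] + dt * k3[m, d]
        _rhs(tmp, k4, t + dt, A, phi, omega, th, Ge, ae, he, Gi, ai, hi,
             wt, wx, wc, L, ox, oc)
        ok = True
        for m in range(M):
            for d in range(D):
                y[m, d] = y[m, d] + (dt / 6.0) * (
                    k1[m, d] + 2.0 * k2[m, d] + 2.0 * k3[m, d] + k4[m, d])
                if not np.isfinite(y[m, d]):
                    ok = False
        out[j + 1] = y
        if not ok:
            return j + 1
    return -1


def _block_offsets(wt: int, wx: int, wc: int, L: int):
    ox = 2 + 16 * wt
    oc = ox + 2 * L * wx
    D = oc + 16 * L * wc
    return ox, oc, D


def _integrate_batch(p: NetworkParams, A: np.ndarray, phi: np.ndarray,
                     f_base: float, T: float, dt: float, which: str,
                     v0: np.ndarray | None = None) -> dict:
    """Integrate the augmented system for a batch of stimuli sharing one grid.

    Returns a dict with 'times', 'V' (nt, M, 2) and, as requested,
    'dv_dtheta' (nt, M, 2, 8), 'dv_dx' (nt, M, 2, 2N),
    'd2v_dxdtheta' (nt, M, 2, 2N, 8).
    """
    if which not in _WHICH:
        raise ValueError(f"unknown which={which!r}")
    wt, wx, wc = _WHICH[which]
    A = np.atleast_2d(np.asarray(A, dtype=float))
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    M, N = A.shape
    L = 2 * N
    omega = 2 * np.pi * f_base * np.arange(1, N + 1)
    ox, oc, D = _block_offsets(wt, wx, wc, L)
    n_steps = int(round(T / dt))
    if v0 is None:
        from .network import find_equilibrium

        eq = find_equilibrium(p, 0.0)
        v0 = eq.as_array()
    y0 = np.zeros((M, D))
    y0[:, 0] = v0[0]
    y0[:, 1] = v0[1]
    out = np.empty((n_steps + 1, M, D))
    gpe, gpi = p.gain_e, p.gain_i
    fail = _rk4(y0, out, n_steps, dt, A, phi, omega, p.theta,
                gpe.Gamma, gpe.a, gpe.h, gpi.Gamma, gpi.a, gpi.h,
                wt, wx, wc, L, ox, oc)
    if fail >= 0:
        t_fail = fail * dt
        bad = ~np.isfinite(out[fail])
        block = "state"
        idx = np.argwhere(bad)
        if idx.size:
            d = int(idx[0, 1])
            if wt and 2 <= d < 18:
                block = "dv_dtheta"
            elif wx and ox <= d < oc:
                block = "dv_dx"
            elif wc and d >= oc:
                block = "d2v_dxdtheta"
        raise IntegrationError(
            f"non-finite {block} sensitivity at t={t_fail:.6g} s",
            t=t_fail, block=block)
    res = {"times": np.arange(n_steps + 1) * dt, "V": out[:, :, 0:2]}
    if wt:
        res["dv_dtheta"] = out[:, :, 2:18].reshape(n_steps + 1, M, 2, 8)
    if wx:
        res["dv_dx"] = out[:, :, ox:ox + 2 * L].reshape(n_steps + 1, M, 2, L)
    if wc:
        res["d2v_dxdtheta"] = out[:, :, oc:].reshape(n_steps + 1, M, 2, L, 8)
    return res


def solve_sensitivities(p: NetworkParams, x: FourierStimulus, T: float | None = None,
                        dt: float = 1e-3, which: str = "all",
                        v0: np.ndarray | None = None
                        ) -> tuple[Trajectory, SensitivityBundle]:
    """State trajectory plus the requested sensitivity blocks for one stimulus.

    `which` selects the integrated blocks: "state", "theta", "x", "theta+x"
    or "all" (cross derivatives require both first-order blocks).  Rate
    derivatives are filled in via :func:`rate_derivatives`.
    """
    if T is None:
        T = x.T
    res = _integrate_batch(p, x.A[None, :], x.phi[None, :], x.f_base, T, dt,
                           which, v0=v0)
    V = res["V"][:, 0, :]
    traj = Trajectory(res["times"], V[:, 0], V[:, 1], gain(V[:, 0], p.gain_e))
    bundle = SensitivityBundle(
        dv_dtheta=res["dv_dtheta"][:, 0] if "dv_dtheta" in res else None,
        dv_dx=res["dv_dx"][:, 0] if "dv_dx" in res else None,
        d2v_dxdtheta=res["d2v_dxdtheta"][:, 0] if "d2v_dxdtheta" in res else None,
    )
    rate_derivatives(traj, bundle, p.gain_e)
    return traj, bundle


def rate_derivatives(traj: Trajectory, bundle: SensitivityBundle,
                     gp: GainParams) -> SensitivityBundle:
    """Map V-sensitivities to rate sensitivities, pointwise in time.

    dr_e/dtheta_k = g'_e(V_e) dV_e/dtheta_k, dr_e/dx_l = g'_e(V_e) dV_e/dx_l,
    and the cross term adds g''_e(V_e) dV_e/dx_l dV_e/dtheta_k.
    """
    g1 = gain(traj.V_e, gp, order=1)
    if bundle.dv_dtheta is not None:
        bundle.dre_dtheta = g1[:, None] * bundle.dv_dtheta[:, 0, :]
    if bundle.dv_dx is not None:
        bundle.dre_dx = g1[:, None] * bundle.dv_dx[:, 0, :]
    if bundle.d2v_dxdtheta is not None:
        if bundle.dv_dtheta is None or bundle.dv_dx is None:
            raise ValueError("cross rate derivatives need both first-order blocks")
        g2 = gain(traj.V_e, gp, order=2)
        bundle.d2re_dxdtheta = (
            g2[:, None, None]
            * bundle.dv_dx[:, 0, :, None]
            * bundle.dv_dtheta[:, 0, None, :]
            + g1[:, None, None] * bundle.d2v_dxdtheta[:, 0, :, :]
        )
    return bundle


def rate_sensitivity_frame(traj: Trajectory, bundle: SensitivityBundle):
    """The eight rate-sensitivity time courses dr_e/dtheta_k as a DataFrame."""
    import pandas as pd

    from .network import THETA_NAMES

    if bundle.dre_dtheta is None:
        raise ValueError("bundle has no parameter rate-sensitivity block")
    cols = {"time": traj.times}
    for k, name in enumerate(THETA_NAMES):
        cols[f"dre_d{name}"] = bundle.dre_dtheta[:, k]
    return pd.DataFrame(cols)
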