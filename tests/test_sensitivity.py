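"""Forward sensitivity systems against finite-difference oracles.

The decisive correctness evidence for the augmented ODE blocks (including
the per-parameter forcing terms) is agreement with central finite
differences of plain simulations started from the same fixed baseline
state; the full multi-instance suite lives in the acceptance tests, this
module spot-checks each block plus the structural zeros.
"""

import numpy as np
import pytest

import eidesign as ed
from eidesign.sensitivity import solve_sensitivities
from conftest import random_bounded_params


@pytest.fixture(scope="module")
def instance(truth, baseline):
    rng = np.random.default_rng(21)
    p = random_bounded_params(rng, truth)
    stim = ed.random_stimulus(ed.StimulusBounds(), 5, 10 / 3, 3.0, rng)
    v0 = ed.find_equilibrium(p, 0.0).as_array()
    traj, bundle = solve_sensitivities(p, stim, 3.0, 1e-3, which="all", v0=v0)
    return p, stim, v0, traj, bundle


def test_bundle_zero_at_time_zero(instance):
    _, _, _, _, b = instance
    assert np.all(b.dv_dtheta[0] == 0)
    assert np.all(b.dv_dx[0] == 0)
    assert np.all(b.d2v_dxdtheta[0] == 0)
    assert np.all(b.dre_dtheta[0] == 0)


def test_zero_stimulus_kills_input_weight_sensitivities(truth):
    stim = ed.FourierStimulus(np.zeros(5), np.zeros(5))
    _, b = solve_sensitivities(truth, stim, 1.0, 1e-3, which="theta")
    assert np.all(b.dv_dtheta[:, :, 2] == 0)   # w_e
    assert np.all(b.dv_dtheta[:, :, 3] == 0)   # w_i


def test_beta_sensitivity_vanishes_at_fixed_point():
    p = ed.NetworkParams(50.0, 25.0, 0, 0, 0, 0, 0, 0)
    stim = ed.FourierStimulus(np.zeros(5), np.zeros(5))
    _, b = solve_sensitivities(p, stim, 1.0, 1e-3, which="theta",
                               v0=np.zeros(2))
    assert np.allclose(b.dv_dtheta[:, 0, 0], 0.0, atol=1e-12)


def _rel(an, fd):
    return np.max(np.abs(an - fd)) / max(np.max(np.abs(fd)), 1e-12)


def test_theta_sensitivities_match_finite_differences(instance):
    p, stim, v0, _, b = instance
    theta = p.theta
    for k in range(8):
        d = 1e-4 * max(abs(theta[k]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[k] += d
        tm[k] -= d
        up, _ = solve_sensitivities(p.with_theta(tp), stim, 3.0, 1e-3, "state", v0=v0)
        um, _ = solve_sensitivities(p.with_theta(tm), stim, 3.0, 1e-3, "state", v0=v0)
        fd = (up.V_e - um.V_e) / (2 * d)
        assert _rel(b.dv_dtheta[:, 0, k], fd) < 1e-3


def test_stimulus_sensitivities_match_finite_differences(instance):
    p, stim, v0, _, b = instance
    x = stim.x
    for l in range(10):
        d = 1e-5 * max(abs(x[l]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[l] += d
        xm[l] -= d
        up, _ = solve_sensitivities(
            p, ed.FourierStimulus.from_x(xp, stim.f_base, stim.T), 3.0, 1e-3,
            "state", v0=v0)
        um, _ = solve_sensitivities(
            p, ed.FourierStimulus.from_x(xm, stim.f_base, stim.T), 3.0, 1e-3,
            "state", v0=v0)
        fd = (up.V_e - um.V_e) / (2 * d)
        assert _rel(b.dv_dx[:, 0, l], fd) < 1e-3


def test_cross_sensitivities_match_differenced_first_order(instance):
    p, stim, v0, _, b = instance
    theta = p.theta
    for k in range(8):
        d = 1e-4 * max(abs(theta[k]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[k] += d
        tm[k] -= d
        _, bp = solve_sensitivities(p.with_theta(tp), stim, 3.0, 1e-3, "x", v0=v0)
        _, bm = solve_sensitivities(p.with_theta(tm), stim, 3.0, 1e-3, "x", v0=v0)
        fd = (bp.dv_dx[:, 0, :] - bm.dv_dx[:, 0, :]) / (2 * d)
        assert _rel(b.d2v_dxdtheta[:, 0, :, k], fd) < 1e-3


def test_rate_derivative_chain_rule(instance):
    p, stim, v0, traj, b = instance
    g1 = ed.gain(traj.V_e, p.gain_e, 1)
    assert np.allclose(b.dre_dtheta, g1[:, None] * b.dv_dtheta[:, 0, :])
    # rate finite difference from plain simulations
    d = 1e-4 * p.theta[2]
    tp, tm = p.theta.copy(), p.theta.copy()
    tp[2] += d
    tm[2] -= d
    up, _ = solve_sensitivities(p.with_theta(tp), stim, 3.0, 1e-3, "state", v0=v0)
    um, _ = solve_sensitivities(p.with_theta(tm), stim, 3.0, 1e-3, "state", v0=v0)
    fd = (up.r_e - um.r_e) / (2 * d)
    assert _rel(b.dre_dtheta[:, 2], fd) < 1e-3


def test_rate_derivative_at_threshold_scaling():
    # at V_e = h_e the chain factor g'(h) is exactly Gamma*a/4 = 1
    from eidesign.network import Trajectory
    from eidesign.sensitivity import SensitivityBundle, rate_derivatives

    times = np.array([0.0, 1.0])
    traj = Trajectory(times, np.array([70.0, 70.0]), np.zeros(2), np.full(2, 50.0))
    dv = np.ones((2, 2, 8))
    b = rate_derivatives(traj, SensitivityBundle(dv_dtheta=dv),
                         ed.DEFAULT_GAIN_E)
    assert np.allclose(b.dre_dtheta, 1.0)


def test_rate_derivatives_requires_blocks():
    from eidesign.network import Trajectory
    from eidesign.sensitivity import SensitivityBundle, rate_derivatives

    times = np.array([0.0, 1.0])
    traj = Trajectory(times, np.zeros(2), np.zeros(2), np.zeros(2))
    bad = SensitivityBundle(d2v_dxdtheta=np.zeros((2, 2, 10, 8)))
    with pytest.raises(ValueError):
        rate_derivatives(traj, bad, ed.DEFAULT_GAIN_E)


def test_rate_sensitivity_frame_layout(instance):
    from eidesign.sensitivity import rate_sensitivity_frame

    _, _, _, traj, b = instance
    df = rate_sensitivity_frame(traj, b)
    assert list(df.columns)[:2] == ["time", "dre_dbeta_e"]
    assert len(df) == traj.times.size
    assert np.allclose(df["dre_dw_e"], b.dre_dtheta[:, 2])


def test_input_weight_dominates_time_constant_sensitivity(truth, baseline):
    """On an information-optimal stimulus the w_e rate-sensitivity dwarfs beta_e's."""
    rng = np.random.default_rng(2)
    stim, _ = ed.design_stimulus(truth, 2, ed.StimulusBounds(), n_starts=2,
                                 rng=rng, dt=0.01, maxiter=60)
    _, b = solve_sensitivities(truth, stim, 3.0, 1e-3, which="theta", v0=baseline)
    assert np.max(np.abs(b.dre_dtheta[:, 2])) > np.max(np.abs(b.dre_dtheta[:, 0]))
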