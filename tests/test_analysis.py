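"""Recovery summaries, likelihood regression, local-optima probability,
confounding curves, error correlations and mode comparison."""

import numpy as np
import pytest

import eidesign as ed
from eidesign.analysis import (
    best_solution_probability,
    compare_modes,
    confounding_curves,
    error_correlations,
    forward_best_probability,
    invert_best_probability,
    likelihood_regression,
    summarize_recovery,
)


# --- recovery summaries -----------------------------------------------------

def test_recovery_exact_estimates_zero_error(truth):
    recs = [truth.theta.copy() for _ in range(3)]
    s = summarize_recovery(recs, truth)
    assert np.allclose(s.table["mean_rel_err_pct"], 0.0)
    assert np.allclose(s.table["std"], 0.0)


def test_recovery_two_point_arithmetic(truth):
    a, b = truth.theta.copy(), truth.theta.copy()
    a[0], b[0] = 49.0, 51.0
    s = summarize_recovery([a, b], truth)
    assert s.table.loc["beta_e", "mean"] == pytest.approx(50.0)
    assert s.table.loc["beta_e", "std"] == pytest.approx(np.sqrt(2.0), rel=1e-12)
    assert s.table.loc["beta_e", "mean_rel_err_pct"] == pytest.approx(2.0)


def test_recovery_needs_two_records(truth):
    with pytest.raises(ValueError):
        summarize_recovery([truth.theta], truth)


# --- likelihood regression --------------------------------------------------

def test_regression_recovers_exact_line():
    M = np.array([8, 40, 80, 120])
    reg = likelihood_regression({
        "optimal": (M, 257.1 * M + 76.2),
        "random": (M, 174.5 * M + 31.1),
    })
    assert reg["optimal"]["slope"] == pytest.approx(257.1, abs=1e-9)
    assert reg["optimal"]["intercept"] == pytest.approx(76.2, abs=1e-7)
    assert reg["random"]["slope"] == pytest.approx(174.5, abs=1e-9)
    assert reg["ratio"] == pytest.approx(257.1 / 174.5, rel=1e-12)
    assert reg["savings"] == pytest.approx(1 - 174.5 / 257.1, rel=1e-12)


def test_regression_flags_degenerate_horizontal_data():
    M = np.array([8, 16, 24])
    reg = likelihood_regression({
        "optimal": (M, np.full(3, 5.0)),
        "random": (M, np.full(3, 5.0)),
    })
    assert reg["degenerate"] is True
    assert reg["ratio"] is None and reg["savings"] is None


def test_regression_needs_three_points():
    with pytest.raises(ValueError):
        likelihood_regression({"optimal": ([8, 16], [1.0, 2.0])})


# --- local-optima probability -----------------------------------------------

def test_identical_runs_give_probability_one(truth):
    ends = [truth.theta.copy() for _ in range(5)]
    res = best_solution_probability(ends, np.ones(5), eta=0.1, n=3,
                                    truth=truth.theta)
    assert res["prob_best"] == 1.0 and res["p"] == 1.0


def test_single_start_probability_is_pass_fraction(truth):
    good = truth.theta.copy()
    bad = truth.theta * 2.0
    ends = [good, good, good, bad]
    res = best_solution_probability(ends, [4, 3, 2, 1], eta=0.1, n=1,
                                    truth=truth.theta)
    assert res["prob_best"] == pytest.approx(0.75)
    assert res["p"] == pytest.approx(0.75)


def test_probability_forward_inverse_identity():
    prob = forward_best_probability(0.3, 5)
    assert prob == pytest.approx(1 - 0.7**5)
    assert invert_best_probability(prob, 5) == pytest.approx(0.3, abs=1e-12)
    for p in np.linspace(0.0, 1.0, 11):
        assert invert_best_probability(forward_best_probability(p, 7), 7) == \
            pytest.approx(p, abs=1e-9)


def test_zero_denominator_flagged_not_crashed():
    ends = [np.array([0.0, 1.0]), np.array([0.0, 1.0])]
    res = best_solution_probability(ends, [1.0, 0.5], eta=0.1, n=1,
                                    truth=np.array([0.0, 1.0]))
    assert res["zero_denominator_flag"] is True
    assert res["prob_best"] == 1.0


# --- confounding -------------------------------------------------------------

@pytest.fixture(scope="module")
def curves(truth):
    eq = ed.find_equilibrium(truth, 0.0)
    return confounding_curves(truth, eq)


def test_confounding_curves_pass_through_truth(curves, truth):
    assert curves[("beta_e", "w_e")](truth.beta_e) == pytest.approx(truth.w_e)
    assert curves[("beta_i", "w_ei")](truth.beta_i) == pytest.approx(truth.w_ei)
    assert curves[("w_ee", "w_ei")](truth.w_ee) == pytest.approx(truth.w_ei)


def test_confounding_curve_values(curves):
    # effective drive beta_e*w_e conserved: 50*1/62.5 = 0.8
    assert curves[("beta_e", "w_e")](62.5) == pytest.approx(0.8)
    # w_ei/beta_i conserved: 2*30/25 = 2.4
    assert curves[("beta_i", "w_ei")](30.0) == pytest.approx(2.4)


def test_confounding_curve_domain_errors(curves):
    with pytest.raises(ZeroDivisionError):
        curves[("beta_e", "w_e")](0.0)


def test_error_correlation_negative_on_confounding_curve(curves, truth):
    beta_hats = np.linspace(40, 60, 12)
    w_hats = curves[("beta_e", "w_e")](beta_hats)
    E = np.tile(truth.theta, (12, 1))
    E[:, 0] = beta_hats
    E[:, 2] = w_hats
    rep = error_correlations({"optimal": E}, truth)
    C = rep.correlations["optimal"]
    assert C.loc["beta_e", "w_e"] < 0
    assert C.loc["beta_e", "beta_e"] == pytest.approx(1.0)
    assert np.allclose(C.values, C.values.T, equal_nan=True)


def test_error_correlations_null_distribution(truth):
    rng = np.random.default_rng(0)
    n = 400
    E = truth.theta + rng.normal(size=(n, 8))
    rep = error_correlations({"random": E}, truth)
    C = rep.correlations["random"].values
    off = C[~np.eye(8, dtype=bool)]
    assert np.all(np.abs(off) < 3 / np.sqrt(n))


def test_constant_estimate_column_reported_missing(truth):
    E = np.tile(truth.theta, (5, 1))
    E[:, 0] += np.arange(5)       # only beta_e varies
    rep = error_correlations({"optimal": E}, truth)
    assert "w_ii" in rep.missing["optimal"]
    assert np.isnan(rep.correlations["optimal"].loc["w_ii", "beta_e"])


# --- mode comparison ----------------------------------------------------------

def test_identical_error_samples_give_p_one():
    e = np.ones((5, 8))
    assert np.all(compare_modes(e, e.copy()) == 1.0)


def test_fully_separated_samples_give_exact_minimal_p():
    lo = np.tile(np.array([1.0, 2, 3, 4, 5]), (8, 1)).T / 100
    hi = lo + 1.0
    p = compare_modes(lo, hi)
    assert np.allclose(p, 2 / 252, rtol=1e-12)   # exact two-sided 5-vs-5 rank-sum


def test_rank_sum_power_on_shifted_distributions():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        opt = np.abs(rng.normal(0.0, 1.0, size=(30, 8)))
        rand = np.abs(rng.normal(0.0, 1.0, size=(30, 8))) + 1.0
        p = compare_modes(opt, rand)
        hits += p.iloc[0] < 0.05
    assert hits >= 18
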