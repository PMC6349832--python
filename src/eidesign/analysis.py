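"""Post-hoc analyses of simulated experiments.

Covers: parameter-recovery summaries across repeated trials, the linear
regression of achieved log-likelihood against the number of stimuli with
the efficiency (slope) ratio of optimal over random designs, the
probability of landing on the best local optimum in multistart
optimization, error-correlation matrices, and the heuristic
parameter-confounding curves for the three strongly coupled pairs
(beta_e, w_e), (beta_i, w_ei) and (w_ee, w_ei).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import NetworkParams, THETA_NAMES, NetworkState, gain

CONFOUNDED_PAIRS = (("beta_e", "w_e"), ("beta_i", "w_ei"), ("w_ee", "w_ei"))


# ---------------------------------------------------------------------------
# recovery summaries


@dataclass
class RecoverySummary:
    """Per-parameter recovery statistics for one mode."""

    table: pd.DataFrame  # index: parameter; columns: mean, std, mean_rel_err_pct

    def __repr__(self):
        return repr(self.table)


def _final_estimates(records) -> np.ndarray:
    ests = [r.final_theta if hasattr(r, "final_theta") else np.asarray(r)
            for r in records]
    ests = [e for e in ests if e is not None]
    if len(ests) < 2:
        raise ValueError("need >= 2 records with final estimates")
    return np.stack(ests)


def summarize_recovery(records, truth: np.ndarray | NetworkParams) -> RecoverySummary:
    """Mean, sample std and mean |relative error| (%) of the final estimates."""
    truth = truth.theta if isinstance(truth, NetworkParams) else np.asarray(truth)
    E = _final_estimates(records)
    rel = np.abs(E - truth) / truth * 100.0
    table = pd.DataFrame(
        {"mean": E.mean(axis=0), "std": E.std(axis=0, ddof=1),
         "mean_rel_err_pct": rel.mean(axis=0)},
        index=list(THETA_NAMES))
    return RecoverySummary(table)


# ---------------------------------------------------------------------------
# likelihood-vs-M regression and efficiency


def likelihood_regression(medians_by_mode: dict) -> dict:
    """OLS of median achieved log-likelihood on the number of stimuli M.

    `medians_by_mode` maps mode name -> (M_values, median_logliks), with at
    least 3 distinct M per mode.  Returns per-mode slope/intercept plus the
    slope ratio optimal/random and the stimulus-savings fraction
    1 - slope_random/slope_optimal.  A degenerate (zero) slope is flagged
    instead of producing NaNs.
    """
    out = {}
    for mode, (M, ll) in medians_by_mode.items():
        M = np.asarray(M, dtype=float)
        ll = np.asarray(ll, dtype=float)
        if np.unique(M).size < 3:
            raise ValueError(f"mode {mode!r}: need >= 3 distinct M values")
        slope, intercept = np.polyfit(M, ll, 1)
        out[mode] = {"slope": float(slope), "intercept": float(intercept)}
    if "optimal" in out and "random" in out:
        s_opt, s_rand = out["optimal"]["slope"], out["random"]["slope"]

        def _tiny(s, mode):
            return abs(s) <= 1e-12 * max(1.0, abs(out[mode]["intercept"]))

        if _tiny(s_rand, "random") or _tiny(s_opt, "optimal"):
            out["ratio"] = None
            out["savings"] = None
            out["degenerate"] = True
        else:
            out["ratio"] = s_opt / s_rand
            out["savings"] = 1.0 - s_rand / s_opt
            out["degenerate"] = False
    return out


# ---------------------------------------------------------------------------
# local-optima probability


def best_solution_probability(endpoints, values, eta: float = 0.1, n: int = 1,
                              truth: np.ndarray | None = None,
                              abs_tol: float = 1e-8) -> dict:
    """Probability of reaching the best local optimum in repeated runs.

    The best endpoint is the one with the highest objective `value`.  A run
    passes when every coordinate i satisfies
    |z_i - z_i_best| / d_i <= eta, with denominator d_i the true value
    (parameter side, `truth` given) or |z_i_best| (stimulus-amplitude side).
    A zero denominator falls back to an absolute tolerance and is flagged.
    Prob("best") is the pass fraction; the per-start probability is
    recovered as p = 1 - (1 - Prob)^(1/n).
    """
    Z = np.stack([np.asarray(e, dtype=float) for e in endpoints])
    values = np.asarray(values, dtype=float)
    if Z.shape[0] < 2:
        raise ValueError("need >= 2 runs")
    best = Z[np.argmax(values)]
    denom = np.abs(np.asarray(truth, dtype=float)) if truth is not None else np.abs(best)
    zero = denom <= 0
    flagged = bool(np.any(zero))
    err = np.abs(Z - best)
    crit = np.where(zero[None, :], err <= abs_tol, err <= eta * denom[None, :])
    passes = crit.all(axis=1)
    prob = float(passes.mean())
    p = invert_best_probability(prob, n)
    return {"prob_best": prob, "p": p, "n": n, "n_runs": int(Z.shape[0]),
            "zero_denominator_flag": flagged}


def forward_best_probability(p: float, n: int) -> float:
    """Probability that at least one of n independent starts finds the best optimum."""
    return 1.0 - (1.0 - p) ** n


def invert_best_probability(prob: float, n: int) -> float:
    """Per-start success probability from the n-start success probability."""
    return 1.0 - (1.0 - prob) ** (1.0 / n)


# ---------------------------------------------------------------------------
# confounding


@dataclass
class ConfoundingReport:
    """Error-correlation matrices per mode and the three predicted curves."""

    correlations: dict  # mode -> DataFrame (8x8, NaN where undefined)
    missing: dict       # mode -> list of parameter names with constant estimates
    highlighted_pairs: tuple = CONFOUNDED_PAIRS


def confounding_curves(truth: NetworkParams, equilibrium: NetworkState) -> dict:
    """The three heuristic confounding relations as evaluable maps.

    Confounding arises because certain parameter combinations act as a unit:
    beta_e*w_e is the effective stimulus drive of the excitatory equation,
    w_ei/beta_i scales the inhibitory feedback, and the net recurrent drive
    w_ee g_e(V_e) - w_ei g_i(V_i) near the equilibrium couples w_ee and w_ei.
    Each returned map sends an estimate of the first pair member to the
    compensating estimate of the second, and passes through the truth point.
    """
    th = truth
    ge_bar = gain(equilibrium.V_e, th.gain_e)
    gi_bar = gain(equilibrium.V_i, th.gain_i)
    if gi_bar == 0:
        raise ZeroDivisionError("g_i at equilibrium is zero")

    def curve_beta_e_w_e(beta_e_hat):
        beta_e_hat = np.asarray(beta_e_hat, dtype=float)
        if np.any(beta_e_hat == 0):
            raise ZeroDivisionError("beta_e_hat must be nonzero")
        return th.beta_e * th.w_e / beta_e_hat

    def curve_beta_i_w_ei(beta_i_hat):
        return th.w_ei * np.asarray(beta_i_hat, dtype=float) / th.beta_i

    def curve_w_ee_w_ei(w_ee_hat):
        net = th.w_ee * ge_bar - th.w_ei * gi_bar
        return (np.asarray(w_ee_hat, dtype=float) * ge_bar - net) / gi_bar

    return {("beta_e", "w_e"): curve_beta_e_w_e,
            ("beta_i", "w_ei"): curve_beta_i_w_ei,
            ("w_ee", "w_ei"): curve_w_ee_w_ei}


def error_correlations(estimates_by_mode: dict, truth: np.ndarray | NetworkParams
                       ) -> ConfoundingReport:
    """Pearson correlations of estimation errors (theta_hat - theta_true).

    `estimates_by_mode` maps mode -> (n_trials, 8) array of final estimates.
    Parameters whose estimates are constant across trials have undefined
    correlations; they are reported as missing (NaN rows/columns).
    """
    truth = truth.theta if isinstance(truth, NetworkParams) else np.asarray(truth)
    cors, missing = {}, {}
    for mode, E in estimates_by_mode.items():
        E = np.asarray(E, dtype=float)
        if E.shape[0] < 3:
            raise ValueError("need >= 3 records per mode")
        err = E - truth
        sd = err.std(axis=0)
        const = sd == 0
        C = np.full((8, 8), np.nan)
        ok = ~const
        if ok.any():
            sub = np.corrcoef(err[:, ok], rowvar=False)
            C[np.ix_(ok, ok)] = np.atleast_2d(sub)
        np.fill_diagonal(C, 1.0)
        C[const, :] = np.nan
        C[:, const] = np.nan
        np.fill_diagonal(C, np.where(const, np.nan, 1.0))
        cors[mode] = pd.DataFrame(C, index=list(THETA_NAMES), columns=list(THETA_NAMES))
        missing[mode] = [THETA_NAMES[i] for i in np.where(const)[0]]
    return ConfoundingReport(correlations=cors, missing=missing)


# ---------------------------------------------------------------------------
# mode comparison


def compare_modes(errors_optimal: np.ndarray, errors_random: np.ndarray) -> pd.Series:
    """Two-sided rank-sum p-value per parameter for optimal vs random errors.

    Inputs are (n_trials, 8) arrays of per-trial error magnitudes.  Uses the
    exact Mann-Whitney/rank-sum distribution when there are no ties.
    """
    eo = np.atleast_2d(np.asarray(errors_optimal, dtype=float))
    er = np.atleast_2d(np.asarray(errors_random, dtype=float))
    if eo.shape[0] < 3 or er.shape[0] < 3:
        raise ValueError("need >= 3 error samples per mode")
    pvals = {}
    for j, name in enumerate(THETA_NAMES):
        a, b = eo[:, j], er[:, j]
        if np.array_equal(np.sort(a), np.sort(b)) and np.unique(a).size == 1:
            pvals[name] = 1.0
            continue
        method = "exact" if np.unique(np.concatenate([a, b])).size == a.size + b.size \
            else "asymptotic"
        pvals[name] = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                               method=method).pvalue)
    return pd.Series(pvals)
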