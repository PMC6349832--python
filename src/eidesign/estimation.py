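"""Multistart bounded maximum-likelihood estimation of the network parameters.

The eight-parameter likelihood surface is maximized over the parameter box
with L-BFGS-B using the analytic spike-train gradient; the optimizer works
in unit-box coordinates (theta scaled by the upper bounds) so the betas
(order 10-100) and the weights (order 1) are comparably conditioned.
Random starts are drawn uniformly inside the bounds; in the closed loop the
previous estimate is passed in as an extra warm start, which can only raise
the achieved likelihood.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .network import NetworkParams
from .spikes import Dataset, log_likelihood_and_gradient

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterBounds:
    """Elementwise box for the 8 network parameters."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != (8,) or hi.shape != (8,) or np.any(lo >= hi):
            raise ValueError("bounds must be 8-vectors with lower < upper")

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper)

    def clip(self, theta) -> np.ndarray:
        return np.clip(theta, self.lower, self.upper)


@dataclass
class MLEResult:
    """Outcome of a multistart likelihood maximization."""

    theta_hat: np.ndarray
    loglik: float
    all_starts: list[dict] = field(default_factory=list)
    n_starts: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "theta_hat": self.theta_hat.tolist(),
            "loglik": self.loglik,
            "n_starts": self.n_starts,
            "all_starts": [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in s.items()} for s in self.all_starts],
        })


def estimate(data: Dataset, bounds: ParameterBounds, n_starts: int = 10,
             rng: np.random.Generator | None = None, dt: float = 1e-3,
             template: NetworkParams | None = None,
             extra_starts: list[np.ndarray] | None = None,
             v0: np.ndarray | None = None,
             maxiter: int = 500, gtol: float = 1e-6) -> MLEResult:
    """Maximum-likelihood fit of the 8 parameters from all accumulated spike trains.

    `template` supplies the fixed gain constants (defaults to the study
    configuration).  `extra_starts` are additional deterministic start
    points (e.g. the previous closed-loop estimate).  `v0` is the known
    pre-stimulus baseline state used for every candidate simulation (see
    :func:`eidesign.spikes.log_likelihood_and_gradient`).  Returns the
    endpoint with the highest achieved log-likelihood over all starts.
    """
    if data.M < 1:
        raise ValueError("need at least one spike train")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if rng is None:
        raise ValueError("a seeded rng is required")
    if template is None:
        from .config import true_params

        template = true_params()
    scale = bounds.upper

    def neg_ll(z):
        p = template.with_theta(bounds.clip(z * scale))
        ll, grad = log_likelihood_and_gradient(data, p, dt, v0=v0)
        return -ll, -grad * scale

    starts = [bounds.sample(rng) for _ in range(n_starts)]
    for th in extra_starts or []:
        starts.append(bounds.clip(np.asarray(th, dtype=float)))
    box = list(zip(bounds.lower / scale, bounds.upper / scale))
    records = []
    best = None
    for s, th0 in enumerate(starts):
        z0 = th0 / scale
        try:
            sol = minimize(neg_ll, z0, jac=True, method="L-BFGS-B", bounds=box,
                           options={"maxiter": maxiter, "gtol": gtol})
            endpoint = bounds.clip(sol.x * scale)
            rec = {"start": np.asarray(th0), "endpoint": endpoint,
                   "value": float(-sol.fun), "converged": bool(sol.success),
                   "nit": int(sol.nit)}
        except Exception as exc:
            logger.warning("MLE start %d failed: %s", s, exc)
            rec = {"start": np.asarray(th0), "endpoint": None,
                   "value": -np.inf, "converged": False, "nit": 0}
        records.append(rec)
        if rec["endpoint"] is not None and (best is None or rec["value"] > best["value"]):
            best = rec
        logger.debug("mle start=%d ll=%.4g nit=%d", s, rec["value"], rec["nit"])
    if best is None:
        raise RuntimeError(f"all {len(starts)} MLE starts diverged: {records}")
    return MLEResult(theta_hat=best["endpoint"], loglik=best["value"],
                     all_starts=records, n_starts=len(starts))
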