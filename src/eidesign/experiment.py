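"""Closed-loop adaptive experiments and the random-stimulus control arm.

One optimal-mode experiment alternates, for i = 1..N_itr and k = 1..8:
design the stimulus maximizing the per-parameter Fisher utility U_k at the
current estimate, present it to the ground-truth network, draw a Poisson
spike train from the elicited rate, and re-estimate all eight parameters by
maximum likelihood from every spike train collected so far.  The total
number of stimuli is therefore 8 * N_itr.  The random arm replaces the
designed stimuli with uniform random Fourier stimuli; its estimation
cadence is configurable (once at the end by default, per-stimulus, or at
checkpoints).

Every random draw flows from the master seed through named streams, so a
record is byte-reproducible and any spike train can be regenerated from its
logged stimulus and seed role.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StimulusConfig, default_stimulus_config, true_params
from .design import design_stimulus
from .estimation import MLEResult, ParameterBounds, estimate
from .network import NetworkParams, THETA_NAMES, find_equilibrium
from .sensitivity import _integrate_batch
from .spikes import Dataset, SpikeTrain, sample_spikes
from .stimulus import FourierStimulus, StimulusBounds, random_stimulus

logger = logging.getLogger(__name__)

# RNG stream roles: every stream is a deterministic function of
# (master seed, role, stimulus index)
ROLE_INIT, ROLE_STIMULUS, ROLE_SPIKES, ROLE_DESIGN, ROLE_MLE = range(5)


def stream(seed: int, role: int, index: int = 0) -> np.random.Generator:
    """Named RNG stream derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, role, index]))


def derive_trial_seed(master_seed: int, trial_index: int) -> int:
    """Per-trial seed, a function of (master seed, trial index) only."""
    return int(np.random.SeedSequence([master_seed, trial_index]).generate_state(1)[0]
               & 0x7FFFFFFF)


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully resolved configuration of one simulated experiment."""

    truth: NetworkParams = field(default_factory=true_params)
    bounds: ParameterBounds = None
    stimulus: StimulusConfig = field(default_factory=default_stimulus_config)
    N_itr: int = 15
    mode: str = "optimal"
    n_starts_design: int = 8
    n_starts_mle: int = 10
    seed: int = 0
    # random-mode only: number of stimuli (defaults to 8*N_itr) and
    # estimation cadence: "end", "every", or a list of checkpoint counts
    M_random: int | None = None
    cadence: object = "end"
    design_maxiter: int = 200
    mle_maxiter: int = 500

    def __post_init__(self):
        if self.bounds is None:
            from .config import default_bounds

            object.__setattr__(self, "bounds", default_bounds())
        if self.N_itr < 1:
            raise ValueError("N_itr must be >= 1")
        if self.mode not in ("optimal", "random"):
            raise ValueError("mode must be 'optimal' or 'random'")

    def to_dict(self) -> dict:
        return {
            "truth": self.truth.theta.tolist(),
            "gain_e": dataclasses.asdict(self.truth.gain_e),
            "gain_i": dataclasses.asdict(self.truth.gain_i),
            "bounds_lower": self.bounds.lower.tolist(),
            "bounds_upper": self.bounds.upper.tolist(),
            "stimulus": dataclasses.asdict(self.stimulus),
            "N_itr": self.N_itr,
            "mode": self.mode,
            "n_starts_design": self.n_starts_design,
            "n_starts_mle": self.n_starts_mle,
            "seed": self.seed,
            "M_random": self.M_random,
            "cadence": self.cadence,
            "design_maxiter": self.design_maxiter,
            "mle_maxiter": self.mle_maxiter,
        }


@dataclass
class ExperimentRecord:
    """Per-stimulus log of one experiment plus the final estimate."""

    config: dict
    entries: list[dict] = field(default_factory=list)
    final_theta: np.ndarray | None = None
    final_loglik: float | None = None

    @property
    def M(self) -> int:
        return len(self.entries)

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            if e["theta_hat"] is None:
                continue
            row = {"index": e["index"], "M": e["index"] + 1, "loglik": e["loglik"]}
            row.update(dict(zip(THETA_NAMES, e["theta_hat"])))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"config": self.config}) + "\n")
            for e in self.entries:
                fh.write(json.dumps(e) + "\n")
            fh.write(json.dumps({
                "final_theta": None if self.final_theta is None
                else self.final_theta.tolist(),
                "final_loglik": self.final_loglik}) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "ExperimentRecord":
        with open(path) as fh:
            lines = [json.loads(l) for l in fh if l.strip()]
        rec = cls(config=lines[0]["config"], entries=lines[1:-1])
        tail = lines[-1]
        if tail.get("final_theta") is not None:
            rec.final_theta = np.asarray(tail["final_theta"])
        rec.final_loglik = tail.get("final_loglik")
        return rec


def _simulate_rate(p: NetworkParams, stim: FourierStimulus, dt: float,
                   v0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from .network import gain

    res = _integrate_batch(p, stim.A[None, :], stim.phi[None, :], stim.f_base,
                           stim.T, dt, "state", v0=v0)
    return res["times"], gain(res["V"][:, 0, 0], p.gain_e)


def run_experiment(cfg: ExperimentConfig) -> ExperimentRecord:
    """Run one closed-loop (or random-control) experiment.

    Failures of individual design or estimation steps are logged and
    substituted (random stimulus / previous estimate) so long runs never die
    mid-way; substitutions are flagged in the record.
    """
    sc = cfg.stimulus
    sbounds = StimulusBounds(A_max=sc.A_max)
    v0 = find_equilibrium(cfg.truth, 0.0).as_array()
    M_total = 8 * cfg.N_itr if cfg.mode == "optimal" else (cfg.M_random or 8 * cfg.N_itr)
    theta_hat = cfg.bounds.sample(stream(cfg.seed, ROLE_INIT))
    record = ExperimentRecord(config=cfg.to_dict())
    data = Dataset()
    loglik = None
    template = cfg.truth

    if cfg.mode == "random":
        if cfg.cadence == "end":
            checkpoints = {M_total}
        elif cfg.cadence == "every":
            checkpoints = set(range(1, M_total + 1))
        else:
            checkpoints = set(int(c) for c in cfg.cadence)
    for m in range(M_total):
        k = m % 8
        substituted = False
        if cfg.mode == "optimal":
            p_hat = template.with_theta(theta_hat)
            try:
                stim, U_k = design_stimulus(
                    p_hat, k, sbounds, sc.N, sc.f_base, sc.T,
                    n_starts=cfg.n_starts_design, rng=stream(cfg.seed, ROLE_DESIGN, m),
                    dt=sc.dt, maxiter=cfg.design_maxiter)
            except Exception as exc:
                logger.warning("design failed at m=%d (%s); random substitute", m, exc)
                stim = random_stimulus(sbounds, sc.N, sc.f_base, sc.T,
                                       stream(cfg.seed, ROLE_STIMULUS, m))
                U_k, substituted = None, True
        else:
            stim = random_stimulus(sbounds, sc.N, sc.f_base, sc.T,
                                   stream(cfg.seed, ROLE_STIMULUS, m))
            U_k = None
        times, rate = _simulate_rate(cfg.truth, stim, sc.dt, v0)
        train = sample_spikes(rate, stim.T, stream(cfg.seed, ROLE_SPIKES, m), times)
        data.append(stim, train)

        do_estimate = cfg.mode == "optimal" or (m + 1) in checkpoints
        est_failed = False
        if do_estimate:
            try:
                res = estimate(data, cfg.bounds, n_starts=cfg.n_starts_mle,
                               rng=stream(cfg.seed, ROLE_MLE, m), dt=sc.dt,
                               template=template, extra_starts=[theta_hat],
                               v0=v0, maxiter=cfg.mle_maxiter)
                theta_hat, loglik = res.theta_hat, res.loglik
            except Exception as exc:
                logger.warning("estimation failed at m=%d (%s); keeping previous", m, exc)
                est_failed = True
        record.entries.append({
            "index": m,
            "k": k if cfg.mode == "optimal" else "random",
            "stimulus": stim.to_dict(),
            "spikes": train.times.tolist(),
            "U_k": U_k,
            "theta_hat": theta_hat.tolist() if do_estimate and not est_failed else (
                theta_hat.tolist() if cfg.mode == "optimal" else None),
            "loglik": loglik,
            "substituted": substituted,
            "estimation_failed": est_failed,
            "seed_roles": {"stimulus": [cfg.seed, ROLE_STIMULUS, m],
                           "spikes": [cfg.seed, ROLE_SPIKES, m],
                           "design": [cfg.seed, ROLE_DESIGN, m],
                           "mle": [cfg.seed, ROLE_MLE, m]},
        })
        logger.info("m=%d/%d mode=%s ll=%s", m + 1, M_total, cfg.mode,
                    "-" if loglik is None else f"{loglik:.1f}")
    record.final_theta = np.asarray(theta_hat)
    record.final_loglik = loglik
    return record


def run_replicates(cfg: ExperimentConfig, n_trials: int, workers: int = 1,
                   start_index: int = 0) -> list[ExperimentRecord]:
    """Independent seeded trials; trial i uses a seed derived from (seed, i).

    Because each trial's seed depends only on the master seed and its global
    index, two batches over disjoint index ranges concatenate into the same
    results as one larger batch.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cfgs = [dataclasses.replace(cfg, seed=derive_trial_seed(cfg.seed, start_index + i))
            for i in range(n_trials)]
    if workers > 1:
        from joblib import Parallel, delayed

        return Parallel(n_jobs=workers)(delayed(run_experiment)(c) for c in cfgs)
    out = []
    for i, c in enumerate(cfgs):
        logger.info("trial %d/%d (seed=%d)", i + 1, n_trials, c.seed)
        try:
            out.append(run_experiment(c))
        except Exception as exc:
            logger.error("trial %d failed: %s", i + 1, exc)
            rec = ExperimentRecord(config=c.to_dict())
            rec.entries = [{"error": str(exc)}]
            out.append(rec)
    return out
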