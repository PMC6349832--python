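# Methods

## Model

The package studies system identification of the simplest recurrent
firing-rate network: one excitatory unit (e) and one inhibitory unit (i)
with membrane-potential-like states `V_e`, `V_i`,

```
dV_e/dt = beta_e * ( -V_e + w_ee g_e(V_e) - w_ei g_i(V_i) + w_e I(t) )
dV_i/dt = beta_i * ( -V_i + w_ie g_e(V_e) - w_ii g_i(V_i) + w_i I(t) )
```

where `g_j(V) = Gamma_j / (1 + exp(-a_j (V - h_j)))` is a logistic gain and
`I(t)` is a scalar stimulus.  The eight estimated parameters are
`theta = [beta_e, beta_i, w_e, w_i, w_ee, w_ei, w_ie, w_ii]`, all
nonnegative (inhibition carries an explicit minus sign in the equations).
The gain constants are treated as known properties of the cell types and
fixed at `Gamma_e=100, a_e=0.04, h_e=70` and `Gamma_i=50, a_i=0.04, h_i=35`
(rates in spikes/s, time in seconds; `beta_e=50 1/s` is a 20 ms time
constant).  Only the excitatory unit is observed, through spike trains from
an inhomogeneous Poisson process with intensity `r_e(t) = g_e(V_e(t))`; the
inhibitory unit is latent, which is what makes the inhibitory parameters
(especially `w_ii`) hard to estimate.

## Stimuli

A stimulus is a truncated Fourier series
`I(t) = sum_{n=1..N} A_n cos(2 pi n f_base t + phi_n)` with parameter
vector `x = [A_1..A_N, phi_1..phi_N]`.  Defaults: `N=5`, `f_base=10/3 Hz`,
duration `T=3 s` (an integer number of base periods), amplitude box
`0 <= A_n <= A_max = 120`.  Phases are unconstrained during optimization
and wrapped to `[-pi, pi)` for storage; wrapping does not change the
waveform.  The nonadaptive control draws `A_n ~ U[0, A_max]` and
`phi_n ~ U[-pi, pi)` independently.

## Likelihood and estimation

For `M` independently presented stimuli with spike trains `S_m`,

```
l(theta) = sum_m [ - int_0^T r_e^{(m)}(t) dt + sum_k ln r_e^{(m)}(t_k^{(m)}) ].
```

The integral uses the trapezoid rule on the simulation grid and spike-time
rates use linear interpolation, so the likelihood and its gradient share
one quadrature.  A rate floor of `1e-9 spikes/s` inside `ln` and `1/r`
guards round-off only (the logistic gain is strictly positive).  The MLE
maximizes `l` over the box (betas in `[0,100]`, input weights in `[0,2]`,
recurrent weights in `[0,3]`) with L-BFGS-B in unit-box coordinates
(`theta` scaled by the upper bounds), analytic gradients, up to 500
iterations per start, projected-gradient tolerance `1e-6`, and `n_starts`
uniform random starts (default 10).  In the closed loop the previous
estimate is always added as a warm start; this can only raise the achieved
likelihood and keeps the multistart contract intact.

### Baseline state

Every presentation starts from the pre-stimulus resting state, the
equilibrium of the autonomous network (`I = 0`), found by damped
fixed-point iteration plus a root polish (residual `< 1e-8`).  When the
likelihood is evaluated at candidate parameters, the baseline state is
treated as a *known input* (the resting state of the preparation the data
was actually collected from) rather than re-derived from each candidate.
This choice makes the zero initial condition of the sensitivity equations
exact, so the analytic likelihood gradient agrees with finite differences
to round-off for all eight parameters; re-equilibrating per candidate
(available by passing `v0=None`) leaves a percent-level inconsistency in
the recurrent-weight components of the gradient because the candidate's
equilibrium moves with those weights.

## Forward sensitivities

Gradients of trajectories are obtained by augmenting the state ODE with
the linear sensitivity systems for `dv/dtheta_k` (8 parameters),
`dv/dx_l` (2N stimulus coordinates) and the cross block
`d2v/dx_l dtheta_k`, each driven by the Jacobian of the vector field plus
a per-parameter forcing term (the braced vector field itself for the
betas, `B e_unit I` for the input weights, signed selections of
`[g_e, g_i]` for the recurrent weights, and their x-differentiated
counterparts for the cross block).  All requested blocks are integrated
jointly with the state by one classical fixed-step RK4 scheme on a shared
grid — the scheme is a package choice; a fixed step guarantees that state,
sensitivities and all quadratures live on the same grid.  Default
`dt = 0.001 s`, configurable; RK4 at `dt = 0.01 s` changes trajectories at
the `1e-6` relative level for this system and is used for the desk-scale
closed-loop studies below.  The integrator core is a compiled (numba)
kernel; it is deterministic, and identical inputs give bit-identical
output.  Rate sensitivities follow by the chain rule through `g_e'` and
`g_e''`.

## Optimal design

The utility of a stimulus for estimating `theta_k` is the time-integrated
Fisher information of the Poisson observation,

```
U_k(x, theta) = int_0^T (1/r_e) (dr_e/dtheta_k)^2 dt,
```

and the trace (A-optimality) utility is `U = sum_k U_k`.  Because the
plain trace is dominated by whichever parameter happens to have small
units, stimuli are designed for one parameter at a time, cycling
k = 1..8.  The analytic gradient of `U_k` in the stimulus coordinates uses
the first-order and cross sensitivity blocks.  Design maximizes `U_k` by
L-BFGS-B over `[0, A_max]^N x R^N` (amplitudes scaled by `A_max`) from
`n_starts` random starts (default 8; the design surface has many local
optima and more starts trade time for quality); ties are broken by lowest
start index for determinism.

## Closed loop

Starting from a uniform random estimate inside the bounds, each iteration
designs 8 stimuli (one per parameter) at the current estimate, collects a
spike train per stimulus from the generating network, and re-estimates
from *all* data collected so far, so `M = 8 N_itr` after `N_itr`
iterations.  Failures of a design or estimation step are logged, the slot
is filled with a random stimulus (or the previous estimate is kept), and
the run continues.  All randomness derives from a master seed through
named streams `(seed, role, stimulus index)`; replicate trials use seeds
derived from `(master seed, trial index)`, so replicate batches over
disjoint index ranges concatenate exactly.

## Synthetic data: what it does and does not emulate

The generator *is* the model: spike trains are exactly inhomogeneous
Poisson (thinning against `max r`, exact for a bounded, linearly
interpolated intensity), responses to different stimuli are exactly
independent, the gain constants are exactly known, and the generating
network lies inside the fitted family.  Passing tests therefore
demonstrate correctness of the machinery and the information advantage of
designed stimuli *under the model's own assumptions*; they say nothing
about refractoriness, adaptation, plasticity, model mismatch, or
non-Poisson variability in real recordings.

## Analyses

* **Recovery tables**: per-parameter mean, sample std, and mean absolute
  relative error (%) of final estimates across trials.
* **Efficiency**: ordinary least squares of the median achieved
  log-likelihood on `M` per mode; the slope ratio optimal/random measures
  the per-stimulus information advantage and `1 - slope_rand/slope_opt`
  the fraction of stimuli saved.  Zero slopes are flagged, not propagated
  as NaNs.
* **Local optima**: with the best endpoint defined by the highest
  objective value, a run passes when every coordinate is within
  `eta = 10%` of the best endpoint (relative to the true value on the
  parameter side, to the best value on the stimulus-amplitude side, with
  an absolute fallback for zero denominators); the per-start success
  probability follows from `Prob(best) = 1 - (1-p)^n`.
* **Confounding**: Pearson correlations of estimation errors across
  trials, plus three parameter-free predicted compensation curves —
  `beta_e w_e` conserved, `w_ei / beta_i` conserved, and the equilibrium
  net recurrent drive `w_ee g_e(V_e) - w_ei g_i(V_i)` conserved — each
  passing exactly through the truth.
* **Mode comparison**: two-sided Wilcoxon rank-sum per parameter (exact
  distribution when tie-free).

## Desk-scale study sizes

Full-scale replication (100 trials x 120 stimuli per mode at
`dt = 0.001 s`) is a cluster-scale computation.  The package's test and
reproduction scripts therefore use scaled-down designs, chosen once:
`dt = 0.01 s` for closed-loop and recovery studies, 10 random-mode trials
with `M = 24` stimuli and 5 MLE starts for the recovery targets, 5
optimal-mode trials with `N_itr = 3` and 4 design starts, likelihood
checkpoints at `M in {8, 16, 24}`, and a 20x10-start probe (at
`dt = 0.02 s`, 150 iterations/start) of the multistart success
probability on one fixed `M = 40` dataset.  Bookkeeping of the full
`M = 120` loop is exercised with a deliberately stripped optimizer budget.

## Known limitations

* Only the two-unit E-I topology is implemented; the generic K-unit
  network is out of scope.
* Gain constants are never estimated.
* D- and E-optimality are not implemented (the trace criterion is the
  method of record here).
* The random arm's per-stimulus estimation cadence is configurable
  because the reference behavior is ambiguous; the default (estimate once
  at the end) is the cheapest and sufficient for recovery comparisons.
* At small `M` the recurrent-weight estimates are strongly confounded;
  this is a property of the estimation problem, not of the optimizer (the
  achieved likelihood exceeds the truth's).
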