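# eidesign

Adaptive, information-optimal stimulus design for identifying
excitatory-inhibitory (E-I) firing-rate networks from spike trains.

## The problem

Fitting even the simplest recurrent network — one excitatory and one
inhibitory unit with logistic gains,

```
dV_e/dt = beta_e ( -V_e + w_ee g_e(V_e) - w_ei g_i(V_i) + w_e I(t) )
dV_i/dt = beta_i ( -V_i + w_ie g_e(V_e) - w_ii g_i(V_i) + w_i I(t) )
```

— is hard when the only observable is a Poisson spike train driven by the
excitatory rate `r_e = g_e(V_e)`: the inhibitory unit is latent, stationary
stimuli carry no information about the time constants, and several
parameter combinations (`beta_e w_e`, `w_ei/beta_i`, the net recurrent
drive) are nearly confounded.  `eidesign` implements the closed-loop remedy:
parameterize the stimulus as a Fourier series
`I(t) = sum_n A_n cos(2 pi n f_base t + phi_n)`, and alternate between

1. **stimulus design** — maximize the per-parameter A-optimal utility
   `U_k(x, theta) = \int_0^T (1/r_e) (dr_e/dtheta_k)^2 dt` (the
   time-integrated Fisher information about `theta_k`) over the stimulus
   parameters `x = [A_1..A_N, phi_1..phi_N]`, cycling k over the eight
   network parameters `theta = [beta_e, beta_i, w_e, w_i, w_ee, w_ei,
   w_ie, w_ii]`; and
2. **estimation** — multistart bounded maximum likelihood of `theta` from
   all spike trains collected so far, with the inhomogeneous-Poisson
   log-likelihood `l = sum_m [-\int r_e^{(m)} dt + sum_k ln r_e^{(m)}(t_k)]`.

All gradients (of trajectories, of `U_k` in the stimulus parameters, of
`l` in `theta`) are exact, obtained by integrating forward sensitivity
ODEs jointly with the state in a compiled fixed-step RK4 kernel.  The
package also ships the nonadaptive random-stimulus control arm and the
post-hoc analyses: recovery tables, likelihood-vs-M efficiency regression,
multistart success probability, and parameter-confounding diagnostics.
It is aimed at computational neuroscientists studying optimal experimental
design for dynamic network identification.

## Worked example

```python
import numpy as np
import eidesign as ed

truth = ed.true_params()            # beta_e=50, beta_i=25, w_e=1, ...

# design a stimulus maximally informative about the input weight w_e
rng = np.random.default_rng(0)
stim, U_opt = ed.design_stimulus(truth, k=2, bounds=ed.StimulusBounds(),
                                 n_starts=4, rng=rng, dt=0.01)
rand = ed.random_stimulus(ed.StimulusBounds(), 5, 10/3, 3.0, rng)
U_rand = ed.utility(rand, truth, k=2, dt=0.01).U_k[2]
print(f"designed U_we = {U_opt:.1f}   random U_we = {U_rand:.1f}")
print("designed amplitudes:", np.round(stim.A, 1))

# a nonadaptive experiment: 24 random stimuli, then maximum likelihood
from eidesign.experiment import ExperimentConfig, run_experiment
from eidesign.config import StimulusConfig
cfg = ExperimentConfig(mode="random", N_itr=1, M_random=24, n_starts_mle=5,
                       seed=1, stimulus=StimulusConfig(dt=0.01))
rec = run_experiment(cfg)
print("final estimate:", np.round(rec.final_theta, 3))
```

Output:

```
designed U_we = 3500.0   random U_we = 58.4
designed amplitudes: [120.   69.5 115.1 120.   53.2]
final estimate: [54.22  19.406  0.9    0.499  0.988  1.548  0.76   0.   ]
```

The designed stimulus carries ~60x more Fisher information about `w_e`
than a random one, and its amplitudes push toward the allowed bound of
120 — a characteristic signature of information-optimal stimuli.  The
24-stimulus nonadaptive fit recovers the well-identified parameters
(`beta_e`, `w_e`) to within ~10% while the weakly identified inhibitory
weights (`w_ii` above) remain poorly constrained at this sample size;
averaged over repeated trials the estimates center on the truth (see
below).

## Command line

```
eidesign simulate --duration 3 --dt 0.001 --out traj.csv
eidesign design-stimulus --seed 0 --k 2 --out stim.json
eidesign run-experiment --seed 0 --n-itr 15 --mode optimal --out run.jsonl
eidesign run-replicates --seed 0 --n-trials 10 --mode random --out runs/
eidesign analyze runs/*.jsonl --out analysis/
eidesign make-fixtures --seed 0 --out fixtures/
```

Each run writes its fully resolved configuration next to its JSON-lines
record; records are byte-reproducible from the master seed.

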