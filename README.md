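# affectdyn

Nonlinear stochastic modelling of daily-life affect dynamics.

Experience-sampling studies beep participants ~10 times a day and ask for
momentary positive-affect (PA) and negative-affect (NA) ratings, yielding
short, irregularly sampled bivariate time series on the unit square.
Their empirical distributions are often skewed, V-shaped or bimodal —
features that the linear Gaussian (vector-autoregressive / Ornstein-
Uhlenbeck) models commonly used in affect research cannot produce.

`affectdyn` implements a free-energy landscape model of the affect system
(a mean-field Ising-type model): PA and NA are the average activations
`y1, y2 in [0, 1]` of two pools of binary units with self-excitation
`Lambda_i`, mutual inhibition `Lambda_12`, thresholds `Theta_i` and pool
sizes `N_i`.  The stationary affect distribution is the Boltzmann density
of the free energy

```
F(y1, y2) = sum_i (-Lambda_i y_i^2 + Theta_i y_i) + Lambda_12 y1 y2
            + sum_i N_i [y_i ln y_i + (1 - y_i) ln(1 - y_i)],
p(y1, y2) = exp(-F) / Z,
```

and the state moves on this landscape by the Langevin dynamics
`dy_i = -D dF/dy_i dt + sqrt(2D) dW_i` with diffusion constant `D`.
Depending on the parameters, `p` is Gaussian-like, skewed, V-shaped or
multimodal (up to four modes).  The package provides:

* the landscape model plus two Gaussian benchmarks (plain and
  unit-square-reflected Ornstein-Uhlenbeck);
* transition (conditional) densities by solving the Fokker-Planck
  equation on the unit square (mass-conservative finite volumes; ADI
  time-stepping and an exact-in-time spectral propagator);
* maximum-likelihood fitting of irregularly sampled series by
  differential evolution;
* the nonlinear feature statistics used to compare models against data:
  sample skewness `m3`, a V-shape curvature index `kappa` (largest
  curvature of the least-squares parabola after a 45-degree rotation),
  and the bimodality coefficient `BC` with its uniform-distribution
  benchmark 5/9;
* parametric bootstrap (90% replicate intervals), a non-parametric
  multimodality bootstrap, and leave-one-out cross-validation with
  pairwise predicted min-log-likelihood differences;
* a synthetic experience-sampling study generator (7 days x 10 beeps,
  stratified random intervals averaging 72 min, 87% compliance, slider
  items averaged into PA/NA scales) with four frozen regime presets.

It is aimed at computational-psychiatry and affect-dynamics researchers
who want a nonlinear, generative alternative to vector-autoregressive
modelling of ESM data.

## Worked example

```python
import numpy as np
from affectdyn import (
    PRESETS, ProtocolSpec, DEConfig,
    generate_subject, fit, summary_stats, parametric_bootstrap,
    stationary_density, find_modes,
)

# one synthetic participant: 7 days x 10 beeps, 87% compliance
subject = generate_subject(PRESETS["bimodal"], ProtocolSpec(), seed=7)
stats = summary_stats(subject)
print(f"n={stats.n_obs}  BC={stats.bc:.3f} ({stats.bc_projection})  "
      f"kappa={stats.kappa:.2f}  rho={stats.rho:.2f}")

# fit the landscape model and inspect the fitted affect distribution
res = fit(subject, "aim", de_config=DEConfig(population=16, generations=20, seed=1))
modes = find_modes(stationary_density(res.estimates, 96), min_prominence=0.05)
print(f"min-log-lik={res.min_log_lik:.1f}  modes={len(modes)}")

# parametric bootstrap: does the fitted model reproduce the observed BC?
(boot,) = parametric_bootstrap(res, subject, ["bc"], n_reps=200, seed=2)
print(f"observed BC={boot.observed:.3f}  90% replicate interval="
      f"({boot.interval[0]:.3f}, {boot.interval[1]:.3f})  covers={boot.covers}")
```

prints

```
n=56  BC=0.600 (pa)  kappa=0.45  rho=-0.23
min-log-lik=-18.6  modes=3
observed BC=0.600  90% replicate interval=(0.538, 0.667)  covers=True
```

This subject answered 56 of 70 beeps; the largest bimodality coefficient
(0.600, on the PA margin) exceeds the 5/9 ~ 0.556 uniform benchmark, the
fitted landscape is multimodal, and the observed bimodality coefficient
falls inside the fitted model's 90% bootstrap band — the landscape model
reproduces the feature it was asked to explain.

A command-line pipeline wraps the same functionality:

```
affectdyn simulate --preset bimodal --n-subjects 10 --seed 1 --out pop.csv
affectdyn fit --input pop.csv --families aim,ou --seed 2 --out fits.csv
affectdyn stats --input pop.csv --out stats.csv
affectdyn cv --input pop.csv --mode fast --seed 3 --out cv.csv
affectdyn compare --input cv.csv --out comparison.csv
```

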