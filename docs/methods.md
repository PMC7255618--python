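# Methods

## The model

`affectdyn` models the momentary affect state of one person as a point
`y = (y1, y2)` on the unit square: `y1` is positive affect (PA) and `y2`
negative affect (NA), each interpreted as the average activation of a pool
of binary stochastic units.  Within-pool excitation, between-pool
inhibition, activation thresholds and the pools' entropy combine into a
free energy

```
F(y1, y2) = sum_i (-Lambda_i y_i^2 + Theta_i y_i) + Lambda_12 y1 y2
            + sum_i (N_i / beta) [y_i ln y_i + (1 - y_i) ln(1 - y_i)]
```

whose Boltzmann factor is the stationary affect distribution
`p(y) = exp(-beta F(y)) / Z`.  The state evolves by the overdamped
Langevin equation

```
dy_i = -beta D (dF/dy_i) dt + sqrt(2 D) dW_i ,
```

so the conditional (transition) density of the state a time `dt` after an
observation solves the corresponding Fokker-Planck equation with the
stationary density as its long-time limit.  `beta` is unidentified and
fixed to 1.  Depending on the parameters the stationary density is
unimodal (Gaussian-like or skewed), bimodal, or V-shaped; with two pools
it can have up to four modes, one per quadrant.

Two Gaussian benchmarks are implemented: a plain Ornstein-Uhlenbeck (OU)
process `dy = -B (y - mu) dt + sigma dW` (exact Gaussian transitions,
probability mass outside the unit square), and a bounded OU variant
confined to the square.  The boundary mechanism of the bounded variant is
a modelling choice: we use reflection (fold-back), which produces the
truncated-Gaussian-like stationary shapes the bounded benchmark is meant
to supply.

### Sign convention for the interaction

`Lambda_12 >= 0` denotes mutual PA-NA inhibition (the `+Lambda_12 y1 y2`
term penalises joint activation), and estimation imposes this lower bound
by default; a `liberated` mode removes it so the data can vote on the
inhibition assumption.  `N_1, N_2` are treated as continuous positive
weights and estimated by continuous optimisation.

## Numerics

### Finite-volume Fokker-Planck generator

Densities live on a cell-centred `m x m` lattice (nodes at
`((i+0.5)/m, (j+0.5)/m)`), which never evaluates the diverging entropic
drift on the boundary.  The jump rate across the face between neighbouring
cells is `(D/h^2) exp(phi_cell - phi_face)` with `phi` the dimensionless
potential (`beta F` for the landscape model; `(y-mu)' B (y-mu) / 2d` for
gradient-form OU), evaluated analytically at cell centres and face
midpoints.  Consequences used throughout:

* zero-flux boundaries conserve mass to solver precision;
* the discrete chain satisfies detailed balance exactly, with stationary
  mass proportional to `exp(-phi)` at the nodes — the discretised
  Boltzmann density is an exact fixed point of the solver;
* the generator is symmetrisable, enabling the spectral propagator below.

Potentials are clipped at 60 units above their minimum before
exponentiation; this flattens the landscape only in regions with
stationary mass below `e^-60` and guards against overflow for extreme
optimizer proposals.

### Time integration

Two integrators share the generator:

* **ADI stepping** (`propagate`): Peaceman-Rachford alternating-direction
  sweeps (Crank-Nicolson accuracy), with an implicit-Euler Rannacher
  start-up (four half-stepped steps) that damps the nonsmooth point
  initial condition.  Step sizes grow geometrically (factor 1.5 from the
  initial 0.5 min, capped at 24 min).  Negative Crank-Nicolson
  undershoots are clipped and the density renormalised; a mass drift
  beyond 1e-4 triggers automatic restarts with halved steps.
* **Spectral propagation** (`SpectralPropagator`): one dense
  eigendecomposition of the symmetrised generator per parameter set, after
  which transition densities are exact in time for arbitrary batches of
  gaps.  This is the likelihood backend: a fit evaluates hundreds of
  parameter sets, each needing ~60 transition densities at scattered
  gaps, and with the eigen-route a full likelihood evaluation costs one
  eigendecomposition plus two small matrix products — ~50 ms at the
  fitting resolution.

The two routes solve the same discrete system and are cross-checked
against each other and against the analytic OU transition (within 2% at
`m = 96` for interior states).

Point observations are mollified to a Gaussian of 1.5 cells before
propagation, so likelihood values are slightly smoothed; `init_width` is
exposed.  Observations on the boundary (raw slider 0 or 100) are nudged
into a 1e-4 shell before readout.

### Resolutions

* standalone transition densities and stationary checks: `m = 96` (default);
* mode counting on fitted landscapes: `m = 96`;
* likelihood evaluation inside optimisation: `m = 24`.  This is coarse but
  self-consistent; per-transition log-densities at `m = 24` agree with
  `m = 64` within ~0.003 nats per observation on interior data, far below
  between-seed likelihood differences at ESM sample sizes.  The
  fitting-scale resolution, optimiser budgets and simulation sizes in the
  test-suite are desk-scale choices, stated where used.

### SDE simulation

The landscape SDE uses Euler-Maruyama (default step 0.25 min) with
adaptive step-halving: a proposed increment that would leave
`(1e-6, 1-1e-6)^2` is halved (up to 40 times, then clamped to the shell).
Plain OU paths are sampled exactly from their Gaussian conditionals;
bounded OU uses Euler-Maruyama with triangular-wave reflection.  Near
entropy-weak boundaries the Euler-Maruyama equilibrium carries an O(dt)
boundary-layer bias; the equilibrium checks for boundary-hugging
parameterizations therefore use a finer step (0.05 min), at which pooled
histograms agree with the Boltzmann density within total-variation 0.05.

## Estimation

The likelihood factorises over Markov transitions; the first observation
is scored by the model's stationary density (an equilibrium-model choice;
`first_obs="condition"` drops the term).  Missing beeps and overnight
pauses simply lengthen the time gap — the continuous-time models need no
special handling (`overnight_weight` can down-weight day-boundary
transitions; default off).  Densities are floored at 1e-300 before logs.

Optimisation: differential evolution (rand/1/bin, F = 0.7, CR = 0.9),
seeded Latin-hypercube initialisation, followed by a Nelder-Mead polish
from the best member.  Everything is deterministic given the seed.  The
default search box is Lambda, Theta in [0, 60], N in [0.1, 60]
(Lambda_12 in [-60, 60] when liberated) with the diffusion constant
searched on a log10 scale over [1e-6, 1] per minute.  Plain OU fits a
full 2x2 drift matrix (stability enforced by an eigenvalue penalty) and a
lower-triangular diffusion factor; the bounded OU is parameterised with a
symmetric positive-definite drift and isotropic diffusion so that its
reflected generator is a gradient flow and the spectral likelihood
applies.

### Identifiability

The seven landscape parameters are heavily over-parameterised relative to
a week of ESM data: over the observed range of each margin the basis
functions `-y^2`, `y` and the entropy term are nearly collinear, so
maximum likelihood constrains the *shape* of the stationary density and
the pace `D` well, but not the individual (Lambda, Theta, N) coordinates —
parameter sets far apart in coordinates can fit indistinguishably or
better than the generating values.  Parameter-recovery studies in the
test-suite therefore fix the nuisance coordinates (Lambda_12, N_1, N_2)
at their generating values and use a physically-informed search box
(Lambda in [0, 15], Theta in [0, 20]); even so, the pooled median
absolute relative error of (Lambda_1, Lambda_2, Theta_1, Theta_2, D) sits near 0.3 at
~60 observations for the frozen skewed preset, shrinking with longer
series (~260 observations).
Conclusions based on fitted *distributions* (bootstrap feature coverage,
predictive comparison) are unaffected by this coordinate degeneracy.

## Feature statistics

* `m3`: bias-corrected sample skewness (G1).  `m4`: bias-corrected excess
  kurtosis (G2).  The exact small-sample corrections follow the standard
  SAS/SPSS convention, consistent with the BC benchmark below in the
  large-n limit.
* Bimodality coefficient `BC = (m3^2 + 1) / (m4 + 3(n-1)^2/((n-2)(n-3)))`,
  in (0, 1]; a uniform sample gives the critical benchmark 5/9.  `BC` is
  computed on four projections — PA, NA and the two diagonals — and the
  maximum is reported with its label, so diagonal bimodality is not
  missed.
* Curvature index `kappa`: z-standardise PA and NA, rotate the cloud
  counterclockwise by 45 degrees, fit a least-squares parabola, and report
  the signed maximal curvature (inverse osculating-circle radius) over the
  observed range of the rotated abscissa.  Upward parabolas (V shapes)
  are positive.  Standardisation tames fortuitous curvatures of compact
  clouds; `kappa` is reported in standardised units.
* `tau` (lag-1 autocorrelation) and RMSSD use successive same-day pairs
  (overnight pairs excluded by default, switchable); `rho` is the PA-NA
  Pearson correlation over all observations.

## Resampling

Parametric bootstrap replicates reuse the original observation times
(same sample size and time structure, which time-dependent statistics
need); intervals are plain 5th-95th percentile bands of the replicates.
Replicates from a plain-OU fit keep their raw (possibly out-of-square)
values, since clamping belongs to the measurement layer, not the model.

The non-parametric multimodality bootstrap resamples observations with
replacement; because the transition likelihood needs strictly increasing
times, the sorted unique draws form the replicate series.  Fits are
repeated per replicate and fitted landscapes with two or more modes
(strict 8-neighbourhood maxima above 5% of the peak, merged within two
cells) are counted.  The prominence threshold is a package choice — no
standard value exists for calling a fitted density multimodal.

Leave-one-out cross-validation predicts each held-out observation from
its predecessor (filter-style conditioning; a two-sided bridge using the
successor as well would be the main alternative): the score is
`-log q(y_t | y_(t-1), dt)` under the model refitted without observation
t, with the stationary density scoring the first observation.  The
`fast` mode fits once on the full series and is flagged approximate; it
is biased toward richer families by roughly p/n nats per observation, a
bias that is an order of magnitude smaller than the model differences it
is used to rank here.

## The synthetic study generator

The generator emulates a standard smartphone ESM protocol: 7 days, 10
beeps/day between 10:00 and 22:00 under a stratified random-interval
scheme (one uniform draw per 72-min stratum; the plain scheme allows
adjacent-strata beeps to fall close together, a `min_gap` option exists,
default off), 87% compliance, and 3 PA / 5 NA slider items (0-100)
averaged per scale and rescaled to [0, 1].  The item-level measurement
layer (clamped Gaussian noise, SD 8 on the slider scale) is an explicit
but deliberately small stand-in for the convention that averaging
integrates measurement noise out; a zero-noise switch exists.

Four frozen presets reproduce the qualitative regimes seen in real ESM
data, validated against the stationary density and the feature
statistics: `gaussian_like` (one interior mode, |m3| small),
`skewed` (one mode, median NA skew ~0.8, broad margins), `bimodal`
(two modes on the anti-diagonal, median max-BC > 5/9), and `vshape`
(strong inhibition, median curvature ~0.6).  Diffusion constants give
lag-1 (~72 min) autocorrelations around 0.4-0.6.  What the generator does
not emulate: response styles and censoring at the slider ends beyond
simple clamping, diurnal cycles, contextual inputs, and between-item
structure — passing tests say nothing about those aspects of real data.

## Known limitations

* Plain OU transition densities are Gaussian on the whole plane, while
  data live in the unit square; this is intentional (it is the benchmark's
  known flaw).
* The Fokker-Planck solver supports diagonal diffusion only; correlated
  instantaneous noise is available in the exact plain-OU sampler but not
  in the grid solver.
* The fast CV mode is in-sample; exact leave-one-out is provided but is
  expensive for the nonlinear family.
* Landscape parameter coordinates are not individually interpretable at
  ESM sample sizes (see Identifiability); report fitted densities and
  features, not raw coordinates.
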