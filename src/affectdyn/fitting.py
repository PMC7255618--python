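"""Maximum-likelihood estimation for the three dynamical model families.

The likelihood of an irregularly sampled series y_1..y_T factorises over
Markov transitions,

    -log L = -log p_first(y_1) - sum_t log q(y_t | y_{t-1}, dt_t),

with q the model's conditional (transition) density over the gap dt_t and
p_first by default the model's stationary density (natural for an
equilibrium model; a config switch conditions on the first observation
instead).  The plain OU family has closed-form Gaussian transitions; the
landscape model and the bounded OU evaluate q with the spectral
Fokker-Planck propagator.  Estimation minimises the min-log-likelihood
with the differential-evolution heuristic (rand/1/bin, F=0.7, CR=0.9)
followed by a Nelder-Mead polish from the best member; everything is
deterministic given the seed.

Optimisation-box defaults: the interaction/threshold/pool-size bounds are
[0, 60] (lambda12 extended to [-60, 60] in "liberated" mode) and the
diffusion constant is searched on a log10 scale over [1e-6, 1] per minute,
which covers unit-square dynamics on experience-sampling time scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import differential_evolution, minimize
from scipy.stats import qmc

from .fokker_planck import SpectralPropagator, TransitionSolverConfig, transition_density
from .model import AIMParameters
from .sde import OUParameters, ou_transition_moments
from .series import AffectTimeSeries

__all__ = [
    "LikelihoodConfig",
    "DEConfig",
    "FitResult",
    "min_log_likelihood",
    "fit",
    "liberate_interaction",
    "FAMILIES",
]

FAMILIES = ("aim", "ou", "bounded_ou")

_DENSITY_FLOOR = 1e-300
_PENALTY = 1e10


@dataclass(frozen=True)
class LikelihoodConfig:
    """Settings of the likelihood assembly.

    ``solver`` controls the Fokker-Planck lattice used for the nonlinear
    families; the default 24-cell lattice is the fitting-scale resolution
    (hundreds of likelihood evaluations per fit), coarse but
    self-consistent - transition densities at this resolution agree with
    the high-resolution solver to a few percent on interior data.
    ``first_obs`` is "stationary" or "condition" (drop the first-
    observation term).  ``overnight_weight`` optionally down-weights
    transitions that span a day boundary (default 1: overnight gaps are
    ordinary long transitions).
    """

    solver: TransitionSolverConfig = field(
        default_factory=lambda: TransitionSolverConfig(grid_size=24, time_step=0.5)
    )
    first_obs: str = "stationary"
    overnight_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.first_obs not in ("stationary", "condition"):
            raise ValueError("first_obs must be 'stationary' or 'condition'")
        if not (0.0 <= self.overnight_weight <= 1.0):
            raise ValueError("overnight_weight must be in [0, 1]")


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution budget (rand/1/bin, F=0.7, CR=0.9)."""

    population: int = 24
    generations: int = 40
    tolerance: float = 1e-3
    seed: int = 0
    polish_maxiter: int = 400

    def __post_init__(self) -> None:
        if self.population < 5:
            raise ValueError("population must be at least 5")
        if self.generations < 1:
            raise ValueError("generations must be at least 1")


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    family: str
    estimates: AIMParameters | OUParameters
    min_log_lik: float
    n_obs: int
    seed: int
    constraint_mode: str = "constrained"
    converged: bool = True
    trace: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.min_log_lik):
            raise ValueError("min_log_lik must be finite")


# ---------------------------------------------------------------------------
# likelihood assembly


def _transition_weights(series: AffectTimeSeries, config: LikelihoodConfig) -> np.ndarray:
    w = np.ones(len(series) - 1)
    if config.overnight_weight < 1.0:
        w[series.day[1:] != series.day[:-1]] = config.overnight_weight
    return w


def _ou_observation_terms(
    params: OUParameters, series: AffectTimeSeries, config: LikelihoodConfig
) -> np.ndarray:
    y = series.y
    dts = series.gaps()
    e, s = ou_transition_moments(params, dts)
    mu = np.asarray(params.mu)
    resid = (y[1:] - mu) - np.einsum("tij,tj->ti", e, y[:-1] - mu)
    det = s[:, 0, 0] * s[:, 1, 1] - s[:, 0, 1] ** 2
    if np.any(det <= 0) or np.any(s[:, 0, 0] <= 0):
        raise FloatingPointError("degenerate OU transition covariance")
    quad = (
        s[:, 1, 1] * resid[:, 0] ** 2
        - 2.0 * s[:, 0, 1] * resid[:, 0] * resid[:, 1]
        + s[:, 0, 0] * resid[:, 1] ** 2
    ) / det
    loglik_t = -0.5 * (quad + np.log(det)) - math.log(2.0 * math.pi)
    if config.first_obs == "stationary":
        s_inf = params.stationary_cov()
        det0 = np.linalg.det(s_inf)
        r0 = y[0] - mu
        quad0 = float(r0 @ np.linalg.solve(s_inf, r0))
        first = -0.5 * (quad0 + math.log(det0)) - math.log(2.0 * math.pi)
    else:
        first = 0.0
    return np.concatenate([[first], loglik_t])


def _gradient_observation_terms(
    model, series: AffectTimeSeries, config: LikelihoodConfig
) -> np.ndarray:
    prop = SpectralPropagator(model, config.solver)
    q = prop.transition_values(series.y[:-1], series.y[1:], series.gaps())
    logs = np.log(np.maximum(q, _DENSITY_FLOOR))
    if config.first_obs == "stationary":
        p0 = prop.stationary_values_at(series.y[:1])[0]
        first = math.log(max(p0, _DENSITY_FLOOR))
    else:
        first = 0.0
    return np.concatenate([[first], logs])


def observation_min_log_liks(
    family: str,
    params: AIMParameters | OUParameters,
    series: AffectTimeSeries,
    config: LikelihoodConfig | None = None,
) -> np.ndarray:
    """Per-observation negative log densities (first obs: stationary term).

    Entry t > 0 is -log q(y_t | y_{t-1}, dt_t); entry 0 is the
    first-observation term (0 when ``first_obs='condition'``).  Summing
    with the overnight weights reproduces :func:`min_log_likelihood`.
    """
    config = config or LikelihoodConfig()
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if family == "ou":
        return -_ou_observation_terms(params, series, config)
    if family == "bounded_ou" and not params.is_gradient(tol=1e-10):
        raise NotImplementedError(
            "per-observation terms require a gradient-form bounded OU"
        )
    return -_gradient_observation_terms(params, series, config)


def min_log_likelihood(
    family: str,
    params: AIMParameters | OUParameters,
    series: AffectTimeSeries,
    config: LikelihoodConfig | None = None,
) -> float:
    """Negative log-likelihood of a series under one model family."""
    config = config or LikelihoodConfig()
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if len(series) < 2:
        raise ValueError("need at least two observations")
    if family == "ou" and (not isinstance(params, OUParameters) or params.bounded):
        raise TypeError("family 'ou' requires unbounded OUParameters")
    if family == "bounded_ou":
        if not isinstance(params, OUParameters) or not params.bounded:
            raise TypeError("family 'bounded_ou' requires bounded OUParameters")
        if not params.is_gradient(tol=1e-10):
            # non-gradient reflected OU: fall back to per-transition ADI
            total = 0.0
            w = _transition_weights(series, config)
            for k in range(len(series) - 1):
                q = transition_density(
                    params, series.y[k], series.y[k + 1], series.gaps()[k],
                    config.solver, method="adi",
                )
                total += w[k] * math.log(max(q, _DENSITY_FLOOR))
            return -total
    if family == "aim" and not isinstance(params, AIMParameters):
        raise TypeError("family 'aim' requires AIMParameters")
    terms = observation_min_log_liks(family, params, series, config)
    weights = np.concatenate([[1.0], _transition_weights(series, config)])
    return float(np.dot(weights, terms))


# ---------------------------------------------------------------------------
# parameter packing


def _aim_bounds(constraint_mode: str) -> list[tuple[float, float]]:
    lo12 = -60.0 if constraint_mode == "liberated" else 0.0
    return [
        (0.0, 60.0),      # lambda1
        (0.0, 60.0),      # lambda2
        (lo12, 60.0),     # lambda12
        (0.0, 60.0),      # theta1
        (0.0, 60.0),      # theta2
        (0.1, 60.0),      # n1
        (0.1, 60.0),      # n2
        (-6.0, 0.0),      # log10 diffusion
    ]


def _aim_unpack(x: np.ndarray, constraint_mode: str) -> AIMParameters:
    return AIMParameters(
        lambda1=x[0], lambda2=x[1], lambda12=x[2], theta1=x[3], theta2=x[4],
        n1=x[5], n2=x[6], diffusion=10.0 ** x[7],
        liberated=constraint_mode == "liberated",
    )


def _aim_pack(p: AIMParameters) -> np.ndarray:
    return np.array(
        [p.lambda1, p.lambda2, p.lambda12, p.theta1, p.theta2, p.n1, p.n2,
         math.log10(p.diffusion)]
    )


_LOG_HALF = math.log10(0.5)


def _ou_bounds() -> list[tuple[float, float]]:
    return [
        (-0.5, 1.5),          # mu1
        (-0.5, 1.5),          # mu2
        (1e-4, 1.0),          # b11
        (1e-4, 1.0),          # b22
        (-0.5, 0.5),          # b12
        (-0.5, 0.5),          # b21
        (-5.0, _LOG_HALF),    # log10 c11
        (-5.0, _LOG_HALF),    # log10 c22
        (-0.5, 0.5),          # c21
    ]


def _ou_unpack(x: np.ndarray) -> OUParameters:
    b = np.array([[x[2], x[4]], [x[5], x[3]]])
    chol = np.array([[10.0 ** x[6], 0.0], [x[8], 10.0 ** x[7]]])
    return OUParameters(mu=(x[0], x[1]), drift_matrix=b, diffusion_chol=chol)


def _bou_bounds() -> list[tuple[float, float]]:
    return [
        (-0.5, 1.5),          # mu1
        (-0.5, 1.5),          # mu2
        (1e-4, 1.0),          # b11
        (1e-4, 1.0),          # b22
        (-0.5, 0.5),          # b12 (symmetric off-diagonal)
        (-5.0, _LOG_HALF),    # log10 isotropic diffusion scale
    ]


def _bou_unpack(x: np.ndarray) -> OUParameters:
    b = np.array([[x[2], x[4]], [x[4], x[3]]])
    s = 10.0 ** x[5]
    return OUParameters(mu=(x[0], x[1]), drift_matrix=b, diffusion_chol=s * np.eye(2), bounded=True)


def _stability_penalty(x: np.ndarray, family: str) -> float:
    if family == "ou":
        b = np.array([[x[2], x[4]], [x[5], x[3]]])
    elif family == "bounded_ou":
        b = np.array([[x[2], x[4]], [x[4], x[3]]])
    else:
        return 0.0
    lam_min = float(np.min(np.real(np.linalg.eigvals(b))))
    if lam_min < 1e-4:
        return _PENALTY * (1.0 + (1e-4 - lam_min))
    return 0.0


def _make_objective(series, family, constraint_mode, config):
    def unpack(x):
        if family == "aim":
            return _aim_unpack(x, constraint_mode)
        if family == "ou":
            return _ou_unpack(x)
        return _bou_unpack(x)

    def objective(x):
        pen = _stability_penalty(x, family)
        if pen:
            return pen
        try:
            params = unpack(x)
            val = min_log_likelihood(family, params, series, config)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            return _PENALTY
        if not math.isfinite(val):
            return _PENALTY
        return val

    return objective, unpack


# ---------------------------------------------------------------------------
# fitting


def _default_bounds(family: str, constraint_mode: str) -> list[tuple[float, float]]:
    if family == "aim":
        return _aim_bounds(constraint_mode)
    if family == "ou":
        return _ou_bounds()
    return _bou_bounds()


def fit(
    series: AffectTimeSeries,
    family: str = "aim",
    bounds: Sequence[tuple[float, float]] | None = None,
    de_config: DEConfig | None = None,
    constraint_mode: str = "constrained",
    config: LikelihoodConfig | None = None,
    warm_start: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood fit of one family to one subject's series.

    Differential evolution over the (possibly user-supplied) bounds box,
    started from a seeded Latin-hypercube population (optionally with a
    warm-start member), followed by a Nelder-Mead polish from the best
    member.  Non-convergence of the DE loop flags the result rather than
    raising.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if constraint_mode not in ("constrained", "liberated"):
        raise ValueError("constraint_mode must be 'constrained' or 'liberated'")
    if len(series) < 10:
        raise ValueError("need at least 10 observations for fitting")
    de = de_config or DEConfig()
    config = config or LikelihoodConfig()
    bounds = list(bounds) if bounds is not None else _default_bounds(family, constraint_mode)
    ndim = len(bounds)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    objective, unpack = _make_objective(series, family, constraint_mode, config)

    sampler = qmc.LatinHypercube(d=ndim, seed=de.seed)
    init = lo + sampler.random(de.population) * (hi - lo)
    if warm_start is not None:
        init[0] = np.clip(np.asarray(warm_start, dtype=float), lo, hi)

    result = differential_evolution(
        objective,
        bounds,
        strategy="rand1bin",
        mutation=0.7,
        recombination=0.9,
        init=init,
        maxiter=de.generations,
        tol=de.tolerance,
        seed=de.seed,
        polish=False,
        updating="immediate",
    )
    if not np.isfinite(result.fun) or result.fun >= _PENALTY:
        raise RuntimeError("all likelihood evaluations were non-finite")

    def clipped_objective(x):
        xc = np.clip(x, lo, hi)
        return objective(xc) + 1e3 * float(np.sum((x - xc) ** 2))

    polish = minimize(
        clipped_objective,
        result.x,
        method="Nelder-Mead",
        options={"maxfev": de.polish_maxiter, "xatol": 1e-4, "fatol": 1e-4},
    )
    if polish.fun <= result.fun:
        best_x, best_f = np.clip(polish.x, lo, hi), float(polish.fun)
    else:
        best_x, best_f = result.x, float(result.fun)

    return FitResult(
        family=family,
        estimates=unpack(best_x),
        min_log_lik=best_f,
        n_obs=len(series),
        seed=de.seed,
        constraint_mode=constraint_mode,
        converged=bool(result.success or polish.success),
        trace={
            "de_nit": int(result.nit),
            "de_nfev": int(result.nfev),
            "polish_nfev": int(polish.nfev),
            "de_fun": float(result.fun),
            "x": best_x.tolist(),
        },
    )


def liberate_interaction(
    fit_constrained: FitResult,
    series: AffectTimeSeries,
    de_config: DEConfig | None = None,
    config: LikelihoodConfig | None = None,
) -> FitResult:
    """Refit with the inhibition bound on lambda12 removed.

    Warm-started from the constrained optimum, so the liberated optimum
    can never be worse (the constrained model is nested).  The trace
    records whether and by how much the interaction crossed zero.
    """
    if fit_constrained.family != "aim":
        raise ValueError("liberation applies to the landscape model only")
    warm = _aim_pack(fit_constrained.estimates)
    out = fit(
        series,
        family="aim",
        de_config=de_config,
        constraint_mode="liberated",
        config=config,
        warm_start=warm,
    )
    lam12 = out.estimates.lambda12
    out.trace["lambda12_crossed_zero"] = bool(lam12 < 0)
    out.trace["lambda12_change"] = float(lam12 - fit_constrained.estimates.lambda12)
    return out
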