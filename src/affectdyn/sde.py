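"""Forward simulation of the affect SDE and of the (bounded) OU benchmarks.

The landscape model evolves by the overdamped Langevin equation

    dy_i = -beta D dF/dy_i dt + sqrt(2 D) dW_i,

integrated with Euler-Maruyama and adaptive step-halving near the edges
(the entropic drift diverges there, so proposed increments that would
leave the open square are shrunk until they stay inside).  The plain OU
benchmark ``dy = -B (y - mu) dt + sigma dW`` is sampled exactly from its
Gaussian conditionals; the bounded OU variant uses Euler-Maruyama with
reflecting (fold-back) boundaries on the unit square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .model import AIMParameters, free_energy_gradient, stationary_density
from .series import AffectTimeSeries

__all__ = [
    "OUParameters",
    "SimulatedPath",
    "simulate_aim",
    "simulate_ou",
    "simulate_bounded_ou",
    "sample_at_times",
    "aim_sample_at_times",
    "ou_sample_at_times",
    "bounded_ou_sample_at_times",
]

EDGE_EPS = 1e-6
MAX_HALVINGS = 40


@dataclass(frozen=True)
class OUParameters:
    """Mean-reverting Gaussian benchmark on the PA-NA plane.

    ``drift_matrix`` B must have eigenvalues with positive real part
    (stability); ``diffusion_chol`` is the lower-triangular factor of the
    instantaneous covariance sigma sigma^T.  With ``bounded=True`` the
    process is confined to the unit square by reflection.
    """

    mu: tuple[float, float]
    drift_matrix: np.ndarray
    diffusion_chol: np.ndarray
    bounded: bool = False

    def __post_init__(self) -> None:
        b = np.asarray(self.drift_matrix, dtype=float)
        c = np.asarray(self.diffusion_chol, dtype=float)
        object.__setattr__(self, "drift_matrix", b)
        object.__setattr__(self, "diffusion_chol", c)
        object.__setattr__(self, "mu", tuple(float(v) for v in self.mu))
        if b.shape != (2, 2) or c.shape != (2, 2):
            raise ValueError("drift_matrix and diffusion_chol must be 2x2")
        if np.any(np.real(np.linalg.eigvals(b)) <= 0):
            raise ValueError("drift matrix must be stable (eigenvalues Re > 0)")
        if c[0, 1] != 0.0 or c[0, 0] <= 0 or c[1, 1] <= 0:
            raise ValueError("diffusion_chol must be lower-triangular with positive diagonal")

    @property
    def instantaneous_cov(self) -> np.ndarray:
        return self.diffusion_chol @ self.diffusion_chol.T

    def stationary_cov(self) -> np.ndarray:
        """Solve B S + S B^T = sigma sigma^T for the stationary covariance."""
        return solve_continuous_lyapunov(self.drift_matrix, self.instantaneous_cov)

    def is_gradient(self, tol: float = 1e-12) -> bool:
        """True when the drift is a gradient flow w.r.t. isotropic diffusion."""
        b = self.drift_matrix
        c = self.instantaneous_cov
        return (
            abs(b[0, 1] - b[1, 0]) <= tol
            and abs(c[0, 1]) <= tol
            and abs(c[0, 0] - c[1, 1]) <= tol
        )


@dataclass
class SimulatedPath:
    """A continuous-time sample path recorded on a dense time grid."""

    times: np.ndarray
    states: np.ndarray
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape != (self.times.size, 2):
            raise ValueError("states must have shape (len(times), 2)")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def step(self) -> float:
        return float(np.min(np.diff(self.times))) if self.times.size > 1 else 0.0


# ---------------------------------------------------------------------------
# sampling helpers


def sample_stationary_aim(
    params: AIMParameters, n: int, rng: np.random.Generator, grid_size: int = 128
) -> np.ndarray:
    """Draw states from the discretised stationary distribution.

    Grid inverse-CDF sampling: a cell is drawn with probability equal to
    its mass and the point is jittered uniformly within the cell.
    """
    grid = stationary_density(params, grid_size)
    m = grid.grid_size
    p = grid.values.ravel()
    p = p / p.sum()
    cells = rng.choice(m * m, size=n, p=p)
    i, j = np.divmod(cells, m)
    u = rng.random((n, 2))
    pts = np.stack([(i + u[:, 0]) * grid.spacing, (j + u[:, 1]) * grid.spacing], axis=1)
    return np.clip(pts, EDGE_EPS, 1.0 - EDGE_EPS)


def _resolve_step(y: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Apply increments, halving any that would leave the open square."""
    prop = y + disp
    outside = np.any((prop <= EDGE_EPS) | (prop >= 1.0 - EDGE_EPS), axis=-1)
    k = 0
    while np.any(outside) and k < MAX_HALVINGS:
        disp = np.where(outside[..., None], 0.5 * disp, disp)
        prop = y + disp
        outside = np.any((prop <= EDGE_EPS) | (prop >= 1.0 - EDGE_EPS), axis=-1)
        k += 1
    return np.clip(prop, EDGE_EPS, 1.0 - EDGE_EPS)


def _aim_em_step(
    params: AIMParameters, y: np.ndarray, dt: float, noise: np.ndarray
) -> np.ndarray:
    drift = -params.beta * params.diffusion * free_energy_gradient(params, y)
    disp = drift * dt + math.sqrt(2.0 * params.diffusion * dt) * noise
    return _resolve_step(y, disp)


def simulate_aim(
    params: AIMParameters,
    t_end: float,
    dt: float = 0.25,
    initial="stationary",
    seed: int | None = None,
) -> SimulatedPath:
    """Euler-Maruyama path of the landscape SDE on [0, t_end] (minutes)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    if isinstance(initial, str):
        if initial != "stationary":
            raise ValueError(f"unknown initial condition {initial!r}")
        y = sample_stationary_aim(params, 1, rng)
    else:
        y = np.clip(np.asarray(initial, dtype=float).reshape(1, 2), EDGE_EPS, 1 - EDGE_EPS)
    n_steps = int(math.ceil(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    states = np.empty((n_steps + 1, 2))
    states[0] = y[0]
    for k in range(n_steps):
        h = min(dt, t_end - k * dt)
        y = _aim_em_step(params, y, h, rng.standard_normal((1, 2)))
        states[k + 1] = y[0]
    times[-1] = t_end
    return SimulatedPath(times, states, rng_seed=seed)


def aim_sample_at_times(
    params: AIMParameters,
    times: np.ndarray,
    n_series: int = 1,
    dt: float = 0.5,
    initial="stationary",
    seed: int | None = None,
) -> np.ndarray:
    """Ensemble of independent landscape paths recorded at given times.

    Used by the parametric bootstrap and equilibrium checks: each of the
    ``n_series`` replicate paths starts from an independent stationary
    draw (or a fixed point) and is stepped with Euler-Maruyama; inter-
    observation gaps are chopped into substeps no longer than ``dt``.
    Returns an array of shape ``(n_series, len(times), 2)``.
    """
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    if isinstance(initial, str):
        y = sample_stationary_aim(params, n_series, rng)
    else:
        init = np.asarray(initial, dtype=float)
        y = np.clip(np.broadcast_to(init, (n_series, 2)).copy(), EDGE_EPS, 1 - EDGE_EPS)
    out = np.empty((n_series, times.size, 2))
    t_prev = 0.0
    for k, t in enumerate(times):
        gap = t - t_prev
        if gap < 0:
            raise ValueError("times must be non-decreasing and non-negative")
        if gap > 0:
            n_sub = max(1, int(math.ceil(gap / dt)))
            h = gap / n_sub
            for _ in range(n_sub):
                y = _aim_em_step(params, y, h, rng.standard_normal((n_series, 2)))
        out[:, k] = y
        t_prev = t
    return out


# ---------------------------------------------------------------------------
# Ornstein-Uhlenbeck


def _expm_neg_bt(b: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """exp(-B dt) for a batch of time gaps, via the closed 2x2 form.

    For any 2x2 matrix M: expm(M) = e^{tr/2} [cosh(q) I + sinh(q)/q (M - tr/2 I)]
    with q = sqrt((tr/2)^2 - det M) (complex-safe; q -> 0 handled by the
    sinc-like limit).
    """
    dts = np.asarray(dts, dtype=float)
    m = -b[None, :, :] * dts[:, None, None]
    tr2 = np.trace(m, axis1=1, axis2=2) / 2.0
    det = m[:, 0, 0] * m[:, 1, 1] - m[:, 0, 1] * m[:, 1, 0]
    q = np.sqrt((tr2**2 - det).astype(complex))
    small = np.abs(q) < 1e-12
    q_safe = np.where(small, 1.0, q)
    shq = np.where(small, 1.0, np.sinh(q_safe) / q_safe)
    chq = np.cosh(q)
    eye = np.eye(2)[None, :, :]
    out = np.exp(tr2)[:, None, None] * (
        chq[:, None, None] * eye + shq[:, None, None] * (m - tr2[:, None, None] * eye)
    )
    return np.real(out)


def ou_transition_moments(params: OUParameters, dts: np.ndarray):
    """Conditional mean propagator and covariance per time gap.

    Returns ``(E, S)`` where the conditional law of ``y(t + dt)`` given
    ``y(t)`` is Gaussian with mean ``mu + E (y - mu)`` and covariance
    ``S = S_inf - E S_inf E^T``.
    """
    e = _expm_neg_bt(params.drift_matrix, np.atleast_1d(dts))
    s_inf = params.stationary_cov()
    s = s_inf[None] - e @ s_inf @ np.transpose(e, (0, 2, 1))
    return e, s


def simulate_ou(
    params: OUParameters,
    times: np.ndarray,
    initial="stationary",
    seed: int | None = None,
) -> SimulatedPath:
    """Exact Gaussian sampling of the plain OU process at given times."""
    if params.bounded:
        raise ValueError("exact sampling applies to the unbounded variant only")
    times = np.asarray(times, dtype=float)
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    states = ou_sample_at_times(params, times, n_series=1, initial=initial, seed=seed)[0]
    return SimulatedPath(times, states, rng_seed=seed)


def ou_sample_at_times(
    params: OUParameters,
    times: np.ndarray,
    n_series: int = 1,
    initial="stationary",
    seed: int | None = None,
) -> np.ndarray:
    """Ensemble of exact OU paths at given times, shape (n_series, n, 2).

    The initial condition sits at t = 0; the process is propagated by its
    Gaussian conditionals over the gaps between 0 and the requested times.
    """
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    mu = np.asarray(params.mu)
    s_inf = params.stationary_cov()
    out = np.empty((n_series, times.size, 2))
    if isinstance(initial, str):
        y = mu + rng.standard_normal((n_series, 2)) @ np.linalg.cholesky(s_inf).T
    else:
        y = np.broadcast_to(np.asarray(initial, dtype=float), (n_series, 2)).copy()
    if times.size == 0:
        return out
    gaps = np.diff(times, prepend=0.0)
    if np.any(gaps < 0):
        raise ValueError("times must be non-negative and non-decreasing")
    e_all, s_all = ou_transition_moments(params, gaps)
    for k in range(times.size):
        if gaps[k] > 0:
            e, s = e_all[k], s_all[k]
            chol = np.linalg.cholesky(s + 1e-18 * np.eye(2))
            mean = mu + (y - mu) @ e.T
            y = mean + rng.standard_normal((n_series, 2)) @ chol.T
        out[:, k] = y
    return out


def _reflect_unit(y: np.ndarray) -> np.ndarray:
    """Fold coordinates back into [0, 1] (triangular-wave reflection)."""
    return 1.0 - np.abs(1.0 - np.mod(y, 2.0))


def simulate_bounded_ou(
    params: OUParameters,
    t_end: float,
    dt: float = 0.25,
    initial="stationary",
    seed: int | None = None,
) -> SimulatedPath:
    """Euler-Maruyama path of the reflected OU process on the unit square."""
    if not params.bounded:
        raise ValueError("params.bounded must be set for the reflected variant")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    states = bounded_ou_sample_at_times(
        params,
        np.arange(int(math.ceil(t_end / dt)) + 1) * dt,
        n_series=1,
        dt=dt,
        initial=initial,
        seed=rng,
    )[0]
    times = np.arange(states.shape[0]) * dt
    return SimulatedPath(times, states, rng_seed=seed)


def bounded_ou_sample_at_times(
    params: OUParameters,
    times: np.ndarray,
    n_series: int = 1,
    dt: float = 0.5,
    initial="stationary",
    seed=None,
) -> np.ndarray:
    """Ensemble of reflected-OU paths recorded at given times."""
    times = np.asarray(times, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = np.asarray(params.mu)
    b = params.drift_matrix
    chol = params.diffusion_chol
    if isinstance(initial, str):
        s_inf = params.stationary_cov()
        y = mu + rng.standard_normal((n_series, 2)) @ np.linalg.cholesky(s_inf).T
        y = _reflect_unit(y)
    else:
        y = _reflect_unit(np.broadcast_to(np.asarray(initial, float), (n_series, 2)).copy())
    out = np.empty((n_series, times.size, 2))
    t_prev = 0.0
    for k, t in enumerate(times):
        gap = t - t_prev
        if gap < 0:
            raise ValueError("times must be non-decreasing and non-negative")
        if gap > 0:
            n_sub = max(1, int(math.ceil(gap / dt)))
            h = gap / n_sub
            sq = math.sqrt(h)
            for _ in range(n_sub):
                drift = -(y - mu) @ b.T
                y = _reflect_unit(y + drift * h + sq * rng.standard_normal((n_series, 2)) @ chol.T)
        out[:, k] = y
        t_prev = t
    return out


def sample_at_times(path: SimulatedPath, times) -> AffectTimeSeries:
    """Read a path at requested beep times (last simulated step not after t).

    For the nearest-step readout to be accurate the path step should be
    small relative to the requested gaps (about 1/50 of the smallest gap);
    the readout error is then within one step's diffusion scale.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return AffectTimeSeries(times, np.empty((0, 2)))
    if times.min() < path.times[0] - 1e-9 or times.max() > path.times[-1] + 1e-9:
        raise ValueError("requested time outside the simulated range")
    idx = np.searchsorted(path.times, times + 1e-9, side="right") - 1
    idx = np.clip(idx, 0, path.times.size - 1)
    y = np.clip(path.states[idx], 0.0, 1.0)
    return AffectTimeSeries(times, y)
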