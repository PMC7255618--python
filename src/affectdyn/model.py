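"""Free-energy landscape model of bivariate affect (the Affective Ising Model).

The affect state ``y = (y1, y2)`` lives on the unit square; ``y1`` is the
average activation of the positive-affect (PA) pool of binary units and
``y2`` that of the negative-affect (NA) pool.  The model is fully
characterised by a free energy

    F(y1, y2) = sum_i (-Lambda_i y_i^2 + Theta_i y_i) + Lambda_12 y1 y2
                + sum_i (N_i / beta) [y_i ln y_i + (1 - y_i) ln(1 - y_i)],

whose Boltzmann factor gives the stationary affect distribution
``p(y) = exp(-beta F(y)) / Z``.  ``Lambda_i >= 0`` are within-pool
self-excitation strengths, ``Lambda_12 >= 0`` the PA-NA mutual-inhibition
strength (negative values = mutual excitation, only allowed in "liberated"
mode), ``Theta_i >= 0`` activation thresholds, ``N_i > 0`` effective pool
sizes, and ``beta`` an inverse temperature that is unidentified and fixed
to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "AIMParameters",
    "AffectState",
    "DensityGrid",
    "ModeSearch",
    "free_energy",
    "free_energy_gradient",
    "stationary_density",
    "find_modes",
]


class AffectState(NamedTuple):
    """A point in the PA-NA plane (both coordinates in [0, 1])."""

    y1: float
    y2: float


@dataclass(frozen=True)
class AIMParameters:
    """Parameters of the affect free energy plus the diffusion constant.

    Attributes
    ----------
    lambda1, lambda2
        Self-excitation strengths of the PA and NA pools (>= 0).
    lambda12
        PA-NA interaction strength.  Non-negative values correspond to
        mutual inhibition; negative values (mutual excitation) are only
        admitted when ``liberated`` is set.
    theta1, theta2
        Activation thresholds (>= 0).
    n1, n2
        Effective pool sizes, treated as continuous positive weights.
    diffusion
        Diffusion constant D (> 0), the pace of affect-state motion per
        minute.  It does not affect the stationary distribution.
    beta
        Inverse temperature; unidentified and therefore fixed to 1.
    liberated
        If True, the inhibition bound ``lambda12 >= 0`` is lifted.
    """

    lambda1: float
    lambda2: float
    lambda12: float
    theta1: float
    theta2: float
    n1: float
    n2: float
    diffusion: float = 1e-3
    beta: float = 1.0
    liberated: bool = False

    def __post_init__(self) -> None:
        if self.beta != 1.0:
            raise ValueError("beta is fixed to 1 (it is unidentified)")
        for name in ("lambda1", "lambda2", "theta1", "theta2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.liberated and self.lambda12 < 0:
            raise ValueError(
                "lambda12 < 0 (mutual excitation) requires liberated=True"
            )
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("pool sizes n1, n2 must be positive")
        if self.diffusion <= 0:
            raise ValueError("diffusion constant must be positive")

    def swapped(self) -> "AIMParameters":
        """Exchange the roles of the PA and NA pools."""
        return AIMParameters(
            lambda1=self.lambda2,
            lambda2=self.lambda1,
            lambda12=self.lambda12,
            theta1=self.theta2,
            theta2=self.theta1,
            n1=self.n2,
            n2=self.n1,
            diffusion=self.diffusion,
            beta=self.beta,
            liberated=self.liberated,
        )


def _xlogx(y: np.ndarray) -> np.ndarray:
    # y ln y with the continuity convention 0 ln 0 = 0
    out = np.zeros_like(y, dtype=float)
    pos = y > 0
    out[pos] = y[pos] * np.log(y[pos])
    return out


def free_energy(params: AIMParameters, state) -> np.ndarray | float:
    """Evaluate the free energy F at one or many affect states.

    ``state`` is a pair ``(y1, y2)`` or an array of shape ``(..., 2)``
    with all values in the closed unit square.  The binary-entropy terms
    are continued to the boundary with ``0 ln 0 = 0``, so F is finite on
    all of [0, 1]^2.
    """
    y = np.asarray(state, dtype=float)
    scalar = y.ndim == 1
    y = np.atleast_2d(y)
    if y.shape[-1] != 2:
        raise ValueError("state must have two coordinates (y1, y2)")
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("affect state outside the unit square")
    y1, y2 = y[..., 0], y[..., 1]
    lam = np.array([params.lambda1, params.lambda2])
    th = np.array([params.theta1, params.theta2])
    n = np.array([params.n1, params.n2])
    f = (
        -lam[0] * y1**2
        + th[0] * y1
        - lam[1] * y2**2
        + th[1] * y2
        + params.lambda12 * y1 * y2
        + (n[0] / params.beta) * (_xlogx(y1) + _xlogx(1.0 - y1))
        + (n[1] / params.beta) * (_xlogx(y2) + _xlogx(1.0 - y2))
    )
    return float(f[0]) if scalar else f


def free_energy_gradient(params: AIMParameters, state) -> np.ndarray:
    """Gradient (dF/dy1, dF/dy2) at interior states.

    The log-odds terms diverge at the edges (they push the state inward),
    so the gradient is only defined on the open square.
    """
    y = np.asarray(state, dtype=float)
    scalar = y.ndim == 1
    y = np.atleast_2d(y)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("gradient undefined on the boundary of the unit square")
    y1, y2 = y[..., 0], y[..., 1]
    g1 = (
        -2.0 * params.lambda1 * y1
        + params.theta1
        + params.lambda12 * y2
        + (params.n1 / params.beta) * np.log(y1 / (1.0 - y1))
    )
    g2 = (
        -2.0 * params.lambda2 * y2
        + params.theta2
        + params.lambda12 * y1
        + (params.n2 / params.beta) * np.log(y2 / (1.0 - y2))
    )
    g = np.stack([g1, g2], axis=-1)
    return g[0] if scalar else g


@dataclass
class DensityGrid:
    """Probability density discretised on a cell-centred m x m lattice.

    Node ``(i, j)`` sits at ``((i + 0.5) h, (j + 0.5) h)`` with
    ``h = 1/m``; axis 0 indexes y1 and axis 1 indexes y2.  ``values``
    are densities per unit area, so the midpoint-rule integral is
    ``values.sum() * h**2``.
    """

    values: np.ndarray
    spacing: float
    z: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("density values must form a square lattice")
        if not math.isclose(self.spacing * self.values.shape[0], 1.0, rel_tol=1e-9):
            raise ValueError("spacing must equal 1/m for an m x m grid on [0,1]^2")
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]

    @property
    def nodes(self) -> np.ndarray:
        m = self.grid_size
        return (np.arange(m) + 0.5) * self.spacing

    def integral(self) -> float:
        return float(self.values.sum() * self.spacing**2)

    def normalized(self) -> "DensityGrid":
        total = self.integral()
        if total <= 0 or not np.isfinite(total):
            raise ValueError("density mass is degenerate; cannot normalize")
        return DensityGrid(self.values / total, self.spacing, z=self.z)

    def interpolate(self, state) -> float:
        """Bilinear interpolation of the density at an interior point."""
        y = np.asarray(state, dtype=float)
        m = self.grid_size
        # fractional index on the cell-centred lattice, clipped to the hull
        fi = np.clip(y / self.spacing - 0.5, 0.0, m - 1.0)
        i0 = np.minimum(fi.astype(int), m - 2)
        t = fi - i0
        v = self.values
        return float(
            v[i0[0], i0[1]] * (1 - t[0]) * (1 - t[1])
            + v[i0[0] + 1, i0[1]] * t[0] * (1 - t[1])
            + v[i0[0], i0[1] + 1] * (1 - t[0]) * t[1]
            + v[i0[0] + 1, i0[1] + 1] * t[0] * t[1]
        )


def stationary_density(params: AIMParameters, grid_size: int = 128) -> DensityGrid:
    """Discretised stationary affect distribution exp(-beta F) / Z.

    The normalizer Z is computed by the midpoint rule and stored on the
    returned grid (``grid.z``).  Exponentials are guarded against
    overflow by subtracting the minimum free energy before exponentiating.
    """
    if grid_size < 2:
        raise ValueError("grid_size too small")
    h = 1.0 / grid_size
    x = (np.arange(grid_size) + 0.5) * h
    yy1, yy2 = np.meshgrid(x, x, indexing="ij")
    pts = np.stack([yy1, yy2], axis=-1)
    f = free_energy(params, pts.reshape(-1, 2)).reshape(grid_size, grid_size)
    fmin = f.min()
    w = np.exp(-params.beta * (f - fmin))
    total = w.sum() * h * h
    if not np.isfinite(total) or total <= 0:
        raise ValueError("degenerate stationary density (extreme parameters)")
    z = total * math.exp(-params.beta * fmin)
    return DensityGrid(w / total, h, z=z)


class ModeSearch(NamedTuple):
    """Result of a mode scan: modes sorted by height, plus a degeneracy flag."""

    modes: list[tuple[AffectState, float]]
    degenerate: bool

    def __len__(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def __getitem__(self, idx):
        return self.modes[idx]


def find_modes(density: DensityGrid, min_prominence: float = 0.05) -> ModeSearch:
    """Locate modes of a discretised density.

    A mode is a strict local maximum over the 8-neighbourhood whose height
    exceeds ``min_prominence`` times the global maximum.  Candidate modes
    closer than two grid cells are merged (the higher one is kept).  A flat
    density has no strict maxima and is returned with ``degenerate=True``.
    """
    if min_prominence < 0:
        raise ValueError("min_prominence must be non-negative")
    v = density.values
    m = density.grid_size
    vmax = v.max()
    if vmax <= 0 or np.ptp(v) < 1e-12 * max(vmax, 1.0):
        return ModeSearch([], degenerate=True)

    # pad with -inf so boundary cells compete only with existing neighbours
    padded = np.full((m + 2, m + 2), -np.inf)
    padded[1:-1, 1:-1] = v
    centre = padded[1:-1, 1:-1]
    strict = np.ones((m, m), dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            neigh = padded[1 + di : 1 + di + m, 1 + dj : 1 + dj + m]
            strict &= centre > neigh
    strict &= v > min_prominence * vmax

    idx = np.argwhere(strict)
    cand = sorted(
        ((v[i, j], i, j) for i, j in idx), key=lambda t: t[0], reverse=True
    )
    kept: list[tuple[float, int, int]] = []
    for height, i, j in cand:
        if all(max(abs(i - ki), abs(j - kj)) >= 2 for _, ki, kj in kept):
            kept.append((height, i, j))
    nodes = density.nodes
    modes = [
        (AffectState(float(nodes[i]), float(nodes[j])), float(height))
        for height, i, j in kept
    ]
    return ModeSearch(modes, degenerate=False)
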