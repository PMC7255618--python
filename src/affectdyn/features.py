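"""Distributional feature statistics of affect time series.

Three statistics target the signature non-Gaussian features of affect
data: the standardized third moment m3 (skew of the PA or NA margins),
a signed curvature index kappa for the V-shaped PA-NA relation, and the
bimodality coefficient

    BC = (m3^2 + 1) / (m4 + 3 (n-1)^2 / ((n-2)(n-3))),

with sample-size-corrected skewness m3 and excess kurtosis m4.  BC lies
in (0, 1]; a uniform distribution gives the customary benchmark
BC_crit = 5/9, values above it point toward bimodality (or heavy skew).
The usual linear summary statistics (lag-1 autocorrelation tau, PA-NA
correlation rho, RMSSD) are computed on successive same-day observation
pairs by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .series import AffectTimeSeries

__all__ = [
    "FeatureStats",
    "standardized_third_moment",
    "excess_kurtosis",
    "bimodality_coefficient",
    "bc_statistic",
    "curvature_index",
    "summary_stats",
    "BC_CRIT",
]

BC_CRIT = 5.0 / 9.0

_SQRT2 = np.sqrt(2.0)


def _validate_sample(x: np.ndarray, n_min: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < n_min:
        raise ValueError(f"need at least {n_min} observations")
    if np.ptp(x) == 0.0:
        raise ValueError("statistic undefined for a constant sample")
    return x


def standardized_third_moment(x) -> float:
    """Bias-corrected sample skewness G1."""
    x = _validate_sample(x, 4)
    return float(sps.skew(x, bias=False))


def excess_kurtosis(x) -> float:
    """Bias-corrected excess kurtosis G2."""
    x = _validate_sample(x, 5)
    return float(sps.kurtosis(x, fisher=True, bias=False))


def bimodality_coefficient(x) -> float:
    """BC = (m3^2 + 1) / (m4 + 3 (n-1)^2 / ((n-2)(n-3)))."""
    x = _validate_sample(x, 5)
    n = x.size
    m3 = sps.skew(x, bias=False)
    m4 = sps.kurtosis(x, fisher=True, bias=False)
    return float((m3**2 + 1.0) / (m4 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


_PROJECTIONS = ("pa", "na", "pa+na", "pa-na")


def bc_statistic(series: AffectTimeSeries | np.ndarray) -> tuple[float, str]:
    """Largest bimodality coefficient over the four marginal projections.

    The four projections are PA, NA and the two diagonals (PA+NA)/sqrt(2)
    and (PA-NA)/sqrt(2); no bimodality along either axis or either
    diagonal then goes unnoticed.  Returns ``(max BC, projection label)``.
    """
    y = series.y if isinstance(series, AffectTimeSeries) else np.asarray(series, float)
    proj = {
        "pa": y[:, 0],
        "na": y[:, 1],
        "pa+na": (y[:, 0] + y[:, 1]) / _SQRT2,
        "pa-na": (y[:, 0] - y[:, 1]) / _SQRT2,
    }
    values = {label: bimodality_coefficient(v) for label, v in proj.items()}
    best = max(_PROJECTIONS, key=lambda lbl: values[lbl])
    return values[best], best


def curvature_index(series: AffectTimeSeries | np.ndarray) -> float:
    """Signed maximal curvature of the least-squares parabola.

    Procedure: (1) z-standardize PA and NA; (2) rotate the cloud
    counterclockwise by 45 degrees, u = (y1 - y2)/sqrt(2),
    v = (y1 + y2)/sqrt(2); (3) fit v = a u^2 + b u + c by least squares;
    (4) return the largest curvature 2|a| / (1 + (2 a u + b)^2)^(3/2) of
    the parabola over the observed u-range (the inverse radius of the
    osculating circle), signed by the parabola's orientation: opening
    upward (V shape) gives kappa > 0, downward gives kappa < 0.
    """
    y = series.y if isinstance(series, AffectTimeSeries) else np.asarray(series, float)
    if y.shape[0] < 10:
        raise ValueError("need at least 10 observations")
    sd = y.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("curvature undefined when a dimension is constant")
    z = (y - y.mean(axis=0)) / sd
    u = (z[:, 0] - z[:, 1]) / _SQRT2
    v = (z[:, 0] + z[:, 1]) / _SQRT2
    if np.ptp(u) == 0:
        raise ValueError("degenerate design: rotated abscissa is constant")
    import warnings

    with warnings.catch_warnings():
        # exactly collinear clouds make the quadratic fit rank-deficient;
        # the zero leading coefficient is the correct answer there
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        a, b, _ = np.polyfit(u, v, 2)
    if a == 0.0:
        return 0.0
    # curvature of v(u) is maximal where |v'| is smallest on [umin, umax]
    vertex = -b / (2.0 * a)
    u_star = np.clip(vertex, u.min(), u.max())
    slope = 2.0 * a * u_star + b
    kappa = 2.0 * abs(a) / (1.0 + slope**2) ** 1.5
    return float(np.sign(a) * kappa)


@dataclass(frozen=True)
class FeatureStats:
    """Flat record of all feature and summary statistics of one series."""

    m3_pa: float
    m3_na: float
    kappa: float
    bc: float
    bc_projection: str
    tau_pa: float
    tau_na: float
    rho: float
    rmssd_pa: float
    rmssd_na: float
    n_obs: int


def _successive_pairs(series: AffectTimeSeries, include_overnight: bool) -> np.ndarray:
    if include_overnight:
        return np.arange(len(series) - 1)
    return series.same_day_pairs()


def summary_stats(
    series: AffectTimeSeries, include_overnight: bool = False
) -> FeatureStats:
    """All feature statistics of a series in one flat record.

    Lag-1 autocorrelations and RMSSD are computed over successive
    same-day observation pairs (overnight gaps excluded unless
    ``include_overnight``); the PA-NA correlation uses all observations.
    """
    if len(series) < 10:
        raise ValueError("need at least 10 observations")
    pairs = _successive_pairs(series, include_overnight)
    if pairs.size < 3:
        raise ValueError("need at least 3 successive same-day pairs")
    y = series.y
    taus = []
    rmssds = []
    for dim in (0, 1):
        x0, x1 = y[pairs, dim], y[pairs + 1, dim]
        if np.ptp(x0) == 0 or np.ptp(x1) == 0:
            taus.append(np.nan)
        else:
            taus.append(float(np.corrcoef(x0, x1)[0, 1]))
        rmssds.append(float(np.sqrt(np.mean((x1 - x0) ** 2))))
    rho = (
        float(np.corrcoef(y[:, 0], y[:, 1])[0, 1])
        if np.ptp(y[:, 0]) > 0 and np.ptp(y[:, 1]) > 0
        else np.nan
    )

    def _maybe(func, *args, default=np.nan):
        # distributional statistics are undefined for degenerate samples;
        # report NaN there instead of losing the defined components
        try:
            return func(*args)
        except ValueError:
            return default

    bc, label = _maybe(bc_statistic, series, default=(np.nan, "undefined"))
    return FeatureStats(
        m3_pa=_maybe(standardized_third_moment, y[:, 0]),
        m3_na=_maybe(standardized_third_moment, y[:, 1]),
        kappa=_maybe(curvature_index, series),
        bc=bc,
        bc_projection=label,
        tau_pa=taus[0],
        tau_na=taus[1],
        rho=rho,
        rmssd_pa=rmssds[0],
        rmssd_na=rmssds[1],
        n_obs=len(series),
    )
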