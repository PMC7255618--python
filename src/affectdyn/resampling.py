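"""Bootstrap evaluation and leave-one-out cross-validation.

Parametric bootstrap: the fitted model replicates the observed study -
``n_reps`` synthetic series are simulated at the original observation
times (same sample size and time structure), each feature statistic is
recomputed per replicate, and the observed statistic is compared with the
replicate median and the 90% interval (5th-95th percentiles).

Non-parametric multimodality bootstrap: whole populations of data sets
are resampled case-wise, each resampled set is refitted, and the
percentage of fitted stationary densities with two or more modes is
recorded per population replicate.

Leave-one-out cross-validation: every observation is predicted from its
predecessor under the maximum-likelihood fit obtained without it; the
average predicted min-log-likelihood (ell-bar) and its between-model
differences (delta ell-bar) measure relative predictive performance.  A
``fast`` mode fits once per family on the full series (flagged
approximate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import features
from .fitting import (
    DEConfig,
    FitResult,
    LikelihoodConfig,
    fit,
    observation_min_log_liks,
)
from .fokker_planck import stationary_grid
from .model import find_modes
from .sde import (
    OUParameters,
    aim_sample_at_times,
    bounded_ou_sample_at_times,
    ou_sample_at_times,
)
from .series import AffectTimeSeries

__all__ = [
    "BootstrapResult",
    "CVResult",
    "parametric_bootstrap",
    "multimodality_bootstrap",
    "loo_cv",
    "compare_population",
    "STATISTICS",
]


# ---------------------------------------------------------------------------
# statistic registry: name -> f(times, y, day) on raw replicate arrays
# (plain OU replicates may leave the unit square; statistics are computed
# on the raw values, clamping is a property of the measurement layer)


def _same_day_pairs(day: np.ndarray) -> np.ndarray:
    return np.nonzero(day[1:] == day[:-1])[0]


def _tau(x: np.ndarray, pairs: np.ndarray) -> float:
    x0, x1 = x[pairs], x[pairs + 1]
    if np.ptp(x0) == 0 or np.ptp(x1) == 0:
        raise ValueError("autocorrelation undefined for constant pairs")
    return float(np.corrcoef(x0, x1)[0, 1])


def _rmssd(x: np.ndarray, pairs: np.ndarray) -> float:
    return float(np.sqrt(np.mean((x[pairs + 1] - x[pairs]) ** 2)))


STATISTICS: dict[str, Callable[[np.ndarray, np.ndarray, np.ndarray], float]] = {
    "m3_pa": lambda t, y, d: features.standardized_third_moment(y[:, 0]),
    "m3_na": lambda t, y, d: features.standardized_third_moment(y[:, 1]),
    "kappa": lambda t, y, d: features.curvature_index(y),
    "bc": lambda t, y, d: features.bc_statistic(y)[0],
    "bc_pa": lambda t, y, d: features.bimodality_coefficient(y[:, 0]),
    "bc_na": lambda t, y, d: features.bimodality_coefficient(y[:, 1]),
    "mean_pa": lambda t, y, d: float(np.mean(y[:, 0])),
    "mean_na": lambda t, y, d: float(np.mean(y[:, 1])),
    "rho": lambda t, y, d: float(np.corrcoef(y[:, 0], y[:, 1])[0, 1]),
    "tau_pa": lambda t, y, d: _tau(y[:, 0], _same_day_pairs(d)),
    "tau_na": lambda t, y, d: _tau(y[:, 1], _same_day_pairs(d)),
    "rmssd_pa": lambda t, y, d: _rmssd(y[:, 0], _same_day_pairs(d)),
    "rmssd_na": lambda t, y, d: _rmssd(y[:, 1], _same_day_pairs(d)),
}


@dataclass
class BootstrapResult:
    """Replicate distribution of one statistic under one fitted model."""

    statistic: str
    observed: float
    replicates: np.ndarray
    median: float
    interval: tuple[float, float]
    n_failed: int
    seed: int | None

    @property
    def covers(self) -> bool:
        """Whether the 90% replicate interval contains the observed value."""
        return self.interval[0] <= self.observed <= self.interval[1]


def _simulate_replicates(
    result: FitResult, times: np.ndarray, n_reps: int, seed, path_dt: float
) -> np.ndarray:
    params = result.estimates
    if result.family == "aim":
        return aim_sample_at_times(params, times, n_reps, dt=path_dt, seed=seed)
    if result.family == "ou":
        return ou_sample_at_times(params, times, n_reps, seed=seed)
    return bounded_ou_sample_at_times(params, times, n_reps, dt=path_dt, seed=seed)


def parametric_bootstrap(
    result: FitResult,
    series: AffectTimeSeries,
    statistics: Sequence[str] = ("m3_pa", "m3_na", "kappa", "bc"),
    n_reps: int = 1000,
    seed: int | None = None,
    path_dt: float = 1.0,
) -> list[BootstrapResult]:
    """Parametric bootstrap of feature statistics under a fitted model.

    Replicated series reuse the original observation times, so replicate
    statistics have the same sample size and time structure as the
    observed one.  Statistic failures on a replicate (for example a
    constant sample) drop that replicate for that statistic and are
    counted in ``n_failed``.
    """
    if n_reps < 50:
        raise ValueError("n_reps must be at least 50")
    unknown = set(statistics) - set(STATISTICS)
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")
    reps = _simulate_replicates(result, series.times, n_reps, seed, path_dt)
    day = series.day
    out = []
    for name in statistics:
        func = STATISTICS[name]
        observed = func(series.times, series.y, day)
        values = []
        failed = 0
        for r in range(n_reps):
            try:
                values.append(func(series.times, reps[r], day))
            except (ValueError, FloatingPointError):
                failed += 1
        values = np.asarray(values)
        lo, hi = np.percentile(values, [5.0, 95.0])
        out.append(
            BootstrapResult(
                statistic=name,
                observed=float(observed),
                replicates=values,
                median=float(np.median(values)),
                interval=(float(lo), float(hi)),
                n_failed=failed,
                seed=seed,
            )
        )
    return out


def multimodality_bootstrap(
    datasets: Sequence[AffectTimeSeries],
    n_population_reps: int = 200,
    seed: int | None = None,
    de_config: DEConfig | None = None,
    config: LikelihoodConfig | None = None,
    min_prominence: float = 0.05,
    grid_size: int = 96,
) -> dict:
    """Non-parametric bootstrap of the percentage of multimodal fits.

    Every population replicate resamples each data set's observations
    with replacement (case resampling; the sorted unique draws form the
    replicate series so that time order is preserved), refits the
    landscape model and counts fitted stationary densities with at least
    two modes.  Returns the replicate percentages with their mean and 90%
    interval; per-dataset fit failures are logged and excluded from that
    replicate's denominator.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    rng = np.random.default_rng(seed)
    de = de_config or DEConfig(population=12, generations=10, polish_maxiter=100)
    percentages = []
    failures = 0
    for _ in range(n_population_reps):
        n_multi = 0
        n_ok = 0
        for ds in datasets:
            idx = np.unique(rng.integers(0, len(ds), size=len(ds)))
            sub = ds.subset(idx)
            try:
                res = fit(sub, "aim", de_config=de, config=config)
                grid = stationary_grid(res.estimates,
                                       _grid_config(config, grid_size))
                n_modes = len(find_modes(grid, min_prominence))
            except (ValueError, RuntimeError):
                failures += 1
                continue
            n_ok += 1
            n_multi += int(n_modes >= 2)
        if n_ok:
            percentages.append(100.0 * n_multi / n_ok)
    percentages = np.asarray(percentages)
    lo, hi = np.percentile(percentages, [5.0, 95.0])
    return {
        "percentages": percentages,
        "mean": float(percentages.mean()),
        "interval": (float(lo), float(hi)),
        "n_failures": failures,
        "seed": seed,
    }


def _grid_config(config: LikelihoodConfig | None, grid_size: int):
    from .fokker_planck import TransitionSolverConfig

    return TransitionSolverConfig(grid_size=grid_size)


@dataclass
class CVResult:
    """Leave-one-out predictive comparison of model families for one series."""

    families: tuple[str, ...]
    ell_bar: dict
    n_points: int
    mode: str
    subject_id: str = "subject"
    n_failed: int = 0

    def delta(self, a: str, b: str) -> float:
        """delta ell-bar = ell_bar(a) - ell_bar(b); negative favours a."""
        return self.ell_bar[a] - self.ell_bar[b]

    def winner(self, a: str, b: str) -> str | None:
        d = self.delta(a, b)
        if d < 0:
            return a
        if d > 0:
            return b
        return None


def loo_cv(
    series: AffectTimeSeries,
    families: Sequence[str] = ("aim", "ou"),
    de_config: DEConfig | None = None,
    config: LikelihoodConfig | None = None,
    seed: int = 0,
    mode: str = "exact",
) -> CVResult:
    """Leave-one-out cross-validation of model families on one series.

    In ``exact`` mode every observation is left out once, each family is
    refitted on the remainder (the held-out point's neighbours become one
    direct long transition), and the held-out observation is predicted
    from its predecessor: ell_t = -log q(y_t | y_{t-1}, dt) under the
    refitted estimate (the first observation is scored by the stationary
    density).  ``fast`` mode fits once per family on the full series and
    scores the same per-observation terms - an approximation, flagged in
    the result.
    """
    if len(series) < 20:
        raise ValueError("need at least 20 observations for cross-validation")
    if mode not in ("exact", "fast"):
        raise ValueError("mode must be 'exact' or 'fast'")
    config = config or LikelihoodConfig()
    de = de_config or DEConfig()
    n = len(series)
    terms: dict[str, np.ndarray] = {}
    if mode == "fast":
        for fam in families:
            res = fit(series, fam, de_config=_seeded(de, seed), config=config)
            terms[fam] = observation_min_log_liks(fam, res.estimates, series, config)
        valid = np.ones(n, dtype=bool)
        failed = 0
    else:
        full = {
            fam: fit(series, fam, de_config=_seeded(de, seed), config=config)
            for fam in families
        }
        terms = {fam: np.full(n, np.nan) for fam in families}
        valid = np.ones(n, dtype=bool)
        for t in range(n):
            reduced = series.drop(t)
            for fam in families:
                try:
                    refit = fit(
                        reduced,
                        fam,
                        de_config=_seeded(de, seed + 1000 + t),
                        config=config,
                        warm_start=np.asarray(full[fam].trace["x"]),
                    )
                    all_terms = observation_min_log_liks(
                        fam, refit.estimates, series, config
                    )
                    terms[fam][t] = all_terms[t]
                except (ValueError, RuntimeError):
                    valid[t] = False
        failed = int(n - valid.sum())
    ell_bar = {fam: float(np.mean(terms[fam][valid])) for fam in families}
    return CVResult(
        families=tuple(families),
        ell_bar=ell_bar,
        n_points=int(valid.sum()),
        mode=mode,
        subject_id=series.subject_id,
        n_failed=failed,
    )


def _seeded(de: DEConfig, seed: int) -> DEConfig:
    return DEConfig(
        population=de.population,
        generations=de.generations,
        tolerance=de.tolerance,
        seed=seed,
        polish_maxiter=de.polish_maxiter,
    )


def compare_population(cv_results: Sequence[CVResult]) -> pd.DataFrame:
    """Pairwise model-comparison table over a population of CV results.

    One row per ordered model pair with the delta ell-bar values and the
    percentage of data sets won by each model (ties split evenly and
    flagged).
    """
    if not cv_results:
        raise ValueError("need at least one CV result")
    families = cv_results[0].families
    rows = []
    for i, a in enumerate(families):
        for b in families[i + 1 :]:
            deltas = np.array([r.delta(a, b) for r in cv_results])
            n = deltas.size
            wins_a = float(np.sum(deltas < 0))
            wins_b = float(np.sum(deltas > 0))
            ties = n - wins_a - wins_b
            rows.append(
                {
                    "model_a": a,
                    "model_b": b,
                    "n_datasets": n,
                    "pct_a_wins": 100.0 * (wins_a + 0.5 * ties) / n,
                    "pct_b_wins": 100.0 * (wins_b + 0.5 * ties) / n,
                    "n_ties": int(ties),
                    "tie_flag": bool(ties),
                    "median_delta": float(np.median(deltas)),
                    "deltas": deltas,
                }
            )
    return pd.DataFrame(rows)
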