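"""Feature statistics: skewness, curvature index, bimodality coefficient."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from affectdyn import (
    AffectTimeSeries,
    BC_CRIT,
    bc_statistic,
    bimodality_coefficient,
    curvature_index,
    standardized_third_moment,
    summary_stats,
)


def g1_by_hand(x):
    """Direct evaluation of the bias-corrected skewness formula."""
    x = np.asarray(x, float)
    n = x.size
    m3_raw = np.mean((x - x.mean()) ** 3)
    s = x.std(ddof=1)
    return n**2 / ((n - 1) * (n - 2)) * m3_raw / s**3


class TestSkewness:
    def test_symmetric_sample_is_zero(self):
        x = np.tile([-1.0, 0.0, 1.0], 30)
        assert standardized_third_moment(x) == pytest.approx(0.0, abs=1e-12)

    def test_exponential_population_value(self, rng):
        x = rng.exponential(size=100_000)
        assert standardized_third_moment(x) == pytest.approx(2.0, abs=0.05)

    def test_formula_oracle_small_sample(self):
        x = [0.0, 0.0, 0.0, 1.0]
        assert standardized_third_moment(x) == pytest.approx(g1_by_hand(x), rel=1e-12)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            standardized_third_moment([1.0] * 10)

    @given(st.lists(st.floats(-10, 10), min_size=5, max_size=50))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_hand_formula(self, xs):
        x = np.asarray(xs)
        if np.ptp(x) == 0:
            return
        assert standardized_third_moment(x) == pytest.approx(
            g1_by_hand(x), rel=1e-9, abs=1e-9
        )


class TestBimodalityCoefficient:
    def test_uniform_benchmark(self, rng):
        x = rng.random(100_000)
        assert bimodality_coefficient(x) == pytest.approx(BC_CRIT, abs=0.01)

    def test_two_point_sample_maximal(self):
        x = np.concatenate([np.zeros(500), np.ones(500)])
        assert bimodality_coefficient(x) == pytest.approx(1.0, abs=0.01)

    def test_normal_sample(self, rng):
        x = rng.standard_normal(100_000)
        assert bimodality_coefficient(x) == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_bounds(self, rng):
        for _ in range(20):
            x = rng.standard_normal(rng.integers(6, 200))
            assert 0.0 < bimodality_coefficient(x) <= 1.0

    def test_separated_mixture_exceeds_critical(self, rng):
        x = np.concatenate([rng.normal(0, 0.3, 400), rng.normal(4, 0.3, 400)])
        assert bimodality_coefficient(x) > BC_CRIT


class TestBCStatistic:
    def test_isotropic_cloud_all_projections_similar(self, rng):
        y = 0.5 + 0.05 * rng.standard_normal((50_000, 2))
        bc, _ = bc_statistic(y)
        assert bc == pytest.approx(1.0 / 3.0, abs=0.02)

    def test_antidiagonal_clusters_found_on_pa_minus_na(self, rng):
        a = np.column_stack([rng.normal(0.8, 0.04, 300), rng.normal(0.2, 0.04, 300)])
        b = np.column_stack([rng.normal(0.2, 0.04, 300), rng.normal(0.8, 0.04, 300)])
        y = np.vstack([a, b])
        bc, label = bc_statistic(y)
        assert label == "pa-na"
        # brute force over the four projections
        projections = {
            "pa": y[:, 0], "na": y[:, 1],
            "pa+na": (y[:, 0] + y[:, 1]) / np.sqrt(2),
            "pa-na": (y[:, 0] - y[:, 1]) / np.sqrt(2),
        }
        best = max(projections, key=lambda k: bimodality_coefficient(projections[k]))
        assert best == label
        assert bc == pytest.approx(bimodality_coefficient(projections[best]))

    def test_max_dominates_single_projection(self, rng):
        y = rng.random((200, 2))
        bc, _ = bc_statistic(y)
        assert bc >= bimodality_coefficient(y[:, 0]) - 1e-12


class TestCurvature:
    def test_straight_line_zero(self):
        y1 = np.linspace(0.1, 0.9, 40)
        y = np.column_stack([y1, 1.0 - y1])
        assert curvature_index(y) == pytest.approx(0.0, abs=1e-8)

    def test_constructed_parabola_vertex_curvature(self):
        # u symmetric about 0, v = a u^2; rotate back to (y1, y2).  After
        # z-standardization both coordinates shrink by the common SD s, so
        # u -> u/s, v -> v/s: the parabola coefficient becomes a*s and the
        # vertex (inside the domain) has curvature 2 a s.
        a = 0.8
        u = np.linspace(-1.0, 1.0, 41)
        v = a * (u**2 - np.mean(u**2))
        y1 = (u + v) / np.sqrt(2)
        y2 = (v - u) / np.sqrt(2)
        s1, s2 = np.std(y1, ddof=1), np.std(y2, ddof=1)
        assert s1 == pytest.approx(s2, rel=1e-9)  # construction keeps symmetry
        kappa = curvature_index(np.column_stack([y1, y2]))
        assert kappa == pytest.approx(2 * a * s1, rel=1e-6)

    def test_downward_parabola_negative(self):
        u = np.linspace(-1.0, 1.0, 41)
        v = -0.5 * (u**2 - np.mean(u**2))
        y = np.column_stack([(u + v) / np.sqrt(2), (v - u) / np.sqrt(2)])
        assert curvature_index(y) < 0

    def test_invariant_under_pa_na_exchange(self, rng):
        y = rng.random((80, 2))
        k1 = curvature_index(y)
        k2 = curvature_index(y[:, ::-1])
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_vertex_outside_domain_uses_endpoint(self):
        # one-sided arm of a parabola: max curvature at the boundary point
        a, b = 0.6, 2.0
        u = np.linspace(0.5, 2.0, 30)
        v = a * u**2 + b * u
        y = np.column_stack([(u + v) / np.sqrt(2), (v - u) / np.sqrt(2)])
        kappa = curvature_index(y)
        # oracle: dense scan of the parabola fitted to the standardized data
        z = (y - y.mean(0)) / y.std(0, ddof=1)
        uu = (z[:, 0] - z[:, 1]) / np.sqrt(2)
        vv = (z[:, 0] + z[:, 1]) / np.sqrt(2)
        aa, bb, _ = np.polyfit(uu, vv, 2)
        grid = np.linspace(uu.min(), uu.max(), 20_000)
        dense = np.max(np.abs(2 * aa) / (1 + (2 * aa * grid + bb) ** 2) ** 1.5)
        assert kappa == pytest.approx(np.sign(aa) * dense, rel=1e-6)


class TestSummaryStats:
    @staticmethod
    def _series(y, gap=60.0):
        n = y.shape[0]
        times = np.arange(n) * gap
        return AffectTimeSeries(times, y, day=np.zeros(n, dtype=int))

    def test_constant_series_rmssd_zero(self):
        y = np.full((12, 2), 0.4)
        st_ = summary_stats(self._series(y))
        assert st_.rmssd_pa == 0.0 and st_.rmssd_na == 0.0
        assert np.isnan(st_.m3_pa)  # skewness undefined for constant sample

    def test_alternating_series_rmssd_one(self):
        y = np.tile([[0.0, 1.0], [1.0, 0.0]], (6, 1))
        st_ = summary_stats(self._series(y))
        assert st_.rmssd_pa == pytest.approx(1.0)
        assert st_.rmssd_na == pytest.approx(1.0)

    def test_loop_oracle(self, rng):
        n = 40
        times = np.sort(rng.uniform(0, 4 * 1440, n))
        y = rng.random((n, 2))
        series = AffectTimeSeries(times, y)
        st_ = summary_stats(series)
        day = np.floor(times / 1440).astype(int)
        pairs = [t for t in range(n - 1) if day[t] == day[t + 1]]
        x0 = np.array([y[t, 0] for t in pairs])
        x1 = np.array([y[t + 1, 0] for t in pairs])
        assert st_.tau_pa == pytest.approx(np.corrcoef(x0, x1)[0, 1])
        assert st_.rmssd_pa == pytest.approx(np.sqrt(np.mean((x1 - x0) ** 2)))
        assert st_.rho == pytest.approx(np.corrcoef(y[:, 0], y[:, 1])[0, 1])

    def test_time_offset_invariance(self, rng):
        n = 30
        times = np.sort(rng.uniform(0, 2 * 1440, n))
        y = rng.random((n, 2))
        a = summary_stats(AffectTimeSeries(times, y))
        b = summary_stats(AffectTimeSeries(times + 5 * 1440.0, y))
        for f in ("m3_pa", "kappa", "bc", "tau_pa", "rho", "rmssd_na"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-12)

    def test_overnight_pairs_excluded_by_default(self):
        times = np.array([0.0, 60.0, 120.0, 1500.0, 1560.0, 1620.0] + list(np.arange(7) * 50 + 2900))
        rng = np.random.default_rng(5)
        y = rng.random((times.size, 2))
        series = AffectTimeSeries(times, y)
        incl = summary_stats(series, include_overnight=True)
        excl = summary_stats(series, include_overnight=False)
        assert incl.rmssd_pa != pytest.approx(excl.rmssd_pa)
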