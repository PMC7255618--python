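"""Path simulation: landscape SDE, exact OU, reflected OU."""

import numpy as np
import pytest
from scipy import stats as sps

from affectdyn import (
    AIMParameters,
    OUParameters,
    free_energy,
    sample_at_times,
    simulate_aim,
    simulate_bounded_ou,
    simulate_ou,
    stationary_density,
)
from affectdyn.sde import (
    aim_sample_at_times,
    bounded_ou_sample_at_times,
    ou_sample_at_times,
    ou_transition_moments,
)


class TestSimulateAim:
    def test_seed_determinism(self, smooth_unimodal):
        a = simulate_aim(smooth_unimodal, 200.0, dt=0.5, seed=42)
        b = simulate_aim(smooth_unimodal, 200.0, dt=0.5, seed=42)
        assert np.array_equal(a.states, b.states)
        c = simulate_aim(smooth_unimodal, 200.0, dt=0.5, seed=43)
        assert not np.array_equal(a.states, c.states)

    def test_paths_stay_inside_open_square(self, smooth_unimodal):
        path = simulate_aim(smooth_unimodal, 2000.0, dt=0.5, seed=7)
        assert np.all(path.states > 0.0) and np.all(path.states < 1.0)

    def test_drift_descends_free_energy(self):
        # the drift term is an exact gradient flow: a noise-free Euler step
        # never increases the free energy (for steps within stability)
        from affectdyn import free_energy_gradient

        p = AIMParameters(3.0, 2.0, 1.0, 2.2, 2.4, 7.0, 8.0, diffusion=1e-3)
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = rng.uniform(0.05, 0.95, 2)
            step = -p.beta * p.diffusion * free_energy_gradient(p, y) * 1.0
            y_new = np.clip(y + step, 1e-9, 1 - 1e-9)
            assert free_energy(p, y_new) <= free_energy(p, y) + 1e-12

    def test_ensemble_mean_free_energy_relaxes(self, smooth_unimodal):
        # started uphill, the ensemble-average free energy decreases toward
        # its equilibrium value (descent within noise tolerance)
        p = smooth_unimodal
        times = np.array([200.0, 1000.0, 3000.0])
        ens = aim_sample_at_times(p, times, n_series=300, dt=0.5,
                                  initial=(0.12, 0.88), seed=1)
        f0 = free_energy(p, np.array([0.12, 0.88]))
        means = [free_energy(p, ens[:, k, :]).mean() for k in range(times.size)]
        assert f0 > means[0] > means[1] > means[2] - 0.05

    def test_invalid_dt(self, smooth_unimodal):
        with pytest.raises(ValueError):
            simulate_aim(smooth_unimodal, 10.0, dt=0.0, seed=0)

    def test_equilibrium_histogram_matches_stationary(self, smooth_unimodal):
        # ensemble started from stationary draws stays in equilibrium:
        # the pooled histogram matches the Boltzmann density in total
        # variation
        times = np.arange(1, 121) * 30.0
        samples = aim_sample_at_times(smooth_unimodal, times, n_series=400, dt=0.5, seed=3)
        pts = samples.reshape(-1, 2)
        m = 16
        hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=m, range=[[0, 1], [0, 1]])
        hist /= hist.sum()
        grid = stationary_density(smooth_unimodal, 96)
        block = grid.values.reshape(m, 6, m, 6).mean(axis=(1, 3)) * grid.spacing**2 * 36
        tv = 0.5 * np.abs(hist - block).sum()
        assert tv < 0.05


class TestSimulateOU:
    def test_short_gap_continuity(self, isotropic_ou):
        path = simulate_ou(isotropic_ou, [0.0, 1e-9], initial=(0.3, 0.6), seed=0)
        assert np.allclose(path.states[1], [0.3, 0.6], atol=1e-5)

    def test_long_gap_matches_stationary_moments(self, asymmetric_ou):
        s_inf = asymmetric_ou.stationary_cov()
        draws = ou_sample_at_times(
            asymmetric_ou, np.array([5000.0]), n_series=10_000,
            initial=(0.2, 0.8), seed=11,
        )[:, 0, :]
        mu_hat = draws.mean(axis=0)
        cov_hat = np.cov(draws.T)
        se = np.sqrt(np.diag(s_inf) / draws.shape[0])
        assert np.all(np.abs(mu_hat - asymmetric_ou.mu) < 5 * se)
        assert np.allclose(cov_hat, s_inf, atol=5e-5, rtol=0.1)

    def test_diagonal_drift_matches_scalar_formulas(self):
        theta, d = 0.05, 3e-4
        ou = OUParameters(
            mu=(0.4, 0.6),
            drift_matrix=theta * np.eye(2),
            diffusion_chol=np.sqrt(2 * d) * np.eye(2),
        )
        e, s = ou_transition_moments(ou, np.array([37.0]))
        assert np.allclose(e[0], np.exp(-theta * 37.0) * np.eye(2))
        var = d / theta * (1 - np.exp(-2 * theta * 37.0))
        assert np.allclose(s[0], var * np.eye(2), rtol=1e-10)

    def test_bounded_flag_rejected(self, isotropic_ou):
        bounded = OUParameters(
            isotropic_ou.mu, isotropic_ou.drift_matrix,
            isotropic_ou.diffusion_chol, bounded=True,
        )
        with pytest.raises(ValueError):
            simulate_ou(bounded, [0.0, 10.0], seed=0)


class TestBoundedOU:
    def test_reflection_keeps_unit_square(self):
        ou = OUParameters(
            mu=(1.3, 0.5),
            drift_matrix=0.03 * np.eye(2),
            diffusion_chol=0.08 * np.eye(2),
            bounded=True,
        )
        path = simulate_bounded_ou(ou, 3000.0, dt=0.5, seed=5)
        assert np.all(path.states >= 0.0) and np.all(path.states <= 1.0)

    def test_interior_process_matches_plain_ou(self, isotropic_ou):
        # small diffusion, mean deep inside: reflections never trigger, so
        # the reflected and plain processes agree in distribution
        bounded = OUParameters(
            isotropic_ou.mu, isotropic_ou.drift_matrix,
            isotropic_ou.diffusion_chol, bounded=True,
        )
        times = np.arange(1, 5) * 400.0
        a = bounded_ou_sample_at_times(bounded, times, 500, dt=0.25, seed=21).reshape(-1, 2)
        b = ou_sample_at_times(isotropic_ou, times, 500, seed=22).reshape(-1, 2)
        for dim in range(2):
            assert sps.ks_2samp(a[:, dim], b[:, dim]).pvalue > 0.01

    def test_outside_mean_concentrates_on_edge(self):
        ou = OUParameters(
            mu=(1.3, 0.5),
            drift_matrix=0.05 * np.eye(2),
            diffusion_chol=0.05 * np.eye(2),
            bounded=True,
        )
        draws = bounded_ou_sample_at_times(
            ou, np.arange(1, 41) * 100.0, 200, dt=0.5, seed=9
        ).reshape(-1, 2)
        assert np.mean(draws[:, 0] > 0.8) > 0.5  # mass piles at the y1 = 1 edge
        assert np.mean(draws[:, 1] > 0.8) < 0.2


class TestSampleAtTimes:
    def test_own_time_stamps_roundtrip(self, smooth_unimodal):
        path = simulate_aim(smooth_unimodal, 100.0, dt=0.5, seed=2)
        series = sample_at_times(path, path.times[10:20])
        assert np.allclose(series.y, path.states[10:20])

    def test_empty_request(self, smooth_unimodal):
        path = simulate_aim(smooth_unimodal, 10.0, dt=0.5, seed=2)
        series = sample_at_times(path, [])
        assert len(series) == 0

    def test_out_of_range_rejected(self, smooth_unimodal):
        path = simulate_aim(smooth_unimodal, 10.0, dt=0.5, seed=2)
        with pytest.raises(ValueError):
            sample_at_times(path, [11.0])

    def test_dense_path_matches_interpolation(self, smooth_unimodal):
        p = smooth_unimodal
        path = simulate_aim(p, 300.0, dt=0.1, initial=(0.5, 0.5), seed=4)
        req = np.array([25.33, 100.77, 250.01])
        series = sample_at_times(path, req)
        interp = np.column_stack(
            [np.interp(req, path.times, path.states[:, k]) for k in range(2)]
        )
        scale = np.sqrt(2 * p.diffusion * 0.1)
        assert np.all(np.abs(series.y - interp) < 3 * scale + 1e-9)


class TestEnsembleHelpers:
    def test_aim_ensemble_deterministic(self, smooth_unimodal):
        t = np.array([10.0, 50.0, 100.0])
        a = aim_sample_at_times(smooth_unimodal, t, 5, dt=1.0, seed=1)
        b = aim_sample_at_times(smooth_unimodal, t, 5, dt=1.0, seed=1)
        assert np.array_equal(a, b)

    def test_weak_convergence_in_step_size(self, smooth_unimodal):
        # halving dt changes the endpoint distribution by less than the
        # Monte-Carlo error of the replicate ensemble
        t = np.array([240.0])
        coarse = aim_sample_at_times(smooth_unimodal, t, 1000, dt=1.0,
                                     initial=(0.5, 0.5), seed=6)[:, 0, 0]
        fine = aim_sample_at_times(smooth_unimodal, t, 1000, dt=0.5,
                                   initial=(0.5, 0.5), seed=7)[:, 0, 0]
        assert sps.ks_2samp(coarse, fine).pvalue > 0.01
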