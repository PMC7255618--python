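"""Likelihood assembly and maximum-likelihood estimation."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from affectdyn import (
    AIMParameters,
    AffectTimeSeries,
    DEConfig,
    LikelihoodConfig,
    OUParameters,
    SpectralPropagator,
    TransitionSolverConfig,
    fit,
    liberate_interaction,
    min_log_likelihood,
    observation_min_log_liks,
)
from affectdyn.esm import ProtocolSpec, generate_subject
from affectdyn.sde import ou_sample_at_times, ou_transition_moments


def _ou_series(ou, n=120, gap=60.0, seed=0):
    times = np.arange(n) * gap
    y = ou_sample_at_times(ou, times, 1, seed=seed)[0]
    return AffectTimeSeries(times, np.clip(y, 0, 1))


class TestOULikelihood:
    def test_matches_joint_gaussian_factorization(self, isotropic_ou):
        series = _ou_series(isotropic_ou, seed=3)
        value = min_log_likelihood("ou", isotropic_ou, series)
        # independent oracle: explicit product of Gaussian conditionals
        mu = np.asarray(isotropic_ou.mu)
        e, s = ou_transition_moments(isotropic_ou, series.gaps())
        total = multivariate_normal(mu, isotropic_ou.stationary_cov()).logpdf(series.y[0])
        for k in range(len(series) - 1):
            mean = mu + e[k] @ (series.y[k] - mu)
            total += multivariate_normal(mean, s[k]).logpdf(series.y[k + 1])
        assert value == pytest.approx(-total, rel=1e-9)

    def test_asymmetric_drift_supported(self, asymmetric_ou):
        series = _ou_series(asymmetric_ou, seed=4)
        assert np.isfinite(min_log_likelihood("ou", asymmetric_ou, series))

    def test_time_gaps_matter(self, isotropic_ou):
        series = _ou_series(isotropic_ou, seed=5)
        stretched = AffectTimeSeries(series.times * 2.0, series.y)
        a = min_log_likelihood("ou", isotropic_ou, series)
        b = min_log_likelihood("ou", isotropic_ou, stretched)
        assert a != pytest.approx(b, rel=1e-6)


class TestAIMLikelihood:
    def test_sum_of_observation_terms(self, smooth_unimodal):
        series = generate_subject(smooth_unimodal, ProtocolSpec(), seed=10)
        cfg = LikelihoodConfig()
        total = min_log_likelihood("aim", smooth_unimodal, series, cfg)
        terms = observation_min_log_liks("aim", smooth_unimodal, series, cfg)
        assert total == pytest.approx(terms.sum(), rel=1e-12)
        # conditioning on the first observation drops exactly that term
        cond = LikelihoodConfig(first_obs="condition")
        assert min_log_likelihood("aim", smooth_unimodal, series, cond) == pytest.approx(
            terms[1:].sum(), rel=1e-10
        )

    def test_no_interaction_transition_factorizes(self):
        # with lambda12 = 0 the two pools are independent, so transition
        # densities satisfy the cross-ratio identity
        # q((a1,a2)->(b1,b2)) q((c1,c2)->(d1,d2))
        #   = q((a1,c2)->(b1,d2)) q((c1,a2)->(d1,b2))
        p = AIMParameters(3.0, 2.0, 0.0, 2.0, 1.5, 5.0, 4.0, diffusion=1e-3)
        prop = SpectralPropagator(p, TransitionSolverConfig(grid_size=32))
        a, b = np.array([0.3, 0.3]), np.array([0.5, 0.4])
        c, d = np.array([0.6, 0.55]), np.array([0.45, 0.7])
        q = prop.transition_values(
            np.array([a, c, [a[0], c[1]], [c[0], a[1]]]),
            np.array([b, d, [b[0], d[1]], [d[0], b[1]]]),
            np.full(4, 80.0),
        )
        assert q[0] * q[1] == pytest.approx(q[2] * q[3], rel=1e-6)

    def test_overnight_downweighting(self, smooth_unimodal):
        series = generate_subject(smooth_unimodal, ProtocolSpec(days=3), seed=11)
        full = min_log_likelihood("aim", smooth_unimodal, series)
        down = min_log_likelihood(
            "aim", smooth_unimodal, series, LikelihoodConfig(overnight_weight=0.0)
        )
        assert down != pytest.approx(full, rel=1e-9)

    def test_family_type_mismatch(self, smooth_unimodal, isotropic_ou):
        series = generate_subject(smooth_unimodal, ProtocolSpec(days=2), seed=12)
        with pytest.raises(TypeError):
            min_log_likelihood("aim", isotropic_ou, series)
        with pytest.raises(TypeError):
            min_log_likelihood("ou", smooth_unimodal, series)


class TestBoundedOULikelihood:
    def test_gradient_form_close_to_plain_ou_inside(self, isotropic_ou):
        # deep inside the square the reflected and plain likelihoods agree
        series = _ou_series(isotropic_ou, n=60, seed=6)
        bounded = OUParameters(
            isotropic_ou.mu, isotropic_ou.drift_matrix,
            isotropic_ou.diffusion_chol, bounded=True,
        )
        cfg = LikelihoodConfig(solver=TransitionSolverConfig(grid_size=48))
        a = min_log_likelihood("ou", isotropic_ou, series)
        b = min_log_likelihood("bounded_ou", bounded, series, cfg)
        assert abs(a - b) / len(series) < 0.02


class TestFit:
    def test_ou_recovers_mean(self, isotropic_ou):
        series = _ou_series(isotropic_ou, n=500, gap=60.0, seed=8)
        res = fit(series, "ou", de_config=DEConfig(population=24, generations=40, seed=2))
        assert res.family == "ou"
        assert np.allclose(res.estimates.mu, isotropic_ou.mu, atol=0.02)

    def test_seed_reproducibility(self, isotropic_ou):
        series = _ou_series(isotropic_ou, n=80, seed=9)
        de = DEConfig(population=12, generations=8, seed=5)
        a = fit(series, "ou", de_config=de)
        b = fit(series, "ou", de_config=de)
        assert a.min_log_lik == b.min_log_lik
        assert np.allclose(a.estimates.mu, b.estimates.mu)
        assert np.array_equal(a.estimates.drift_matrix, b.estimates.drift_matrix)

    def test_too_short_series_rejected(self, isotropic_ou):
        series = _ou_series(isotropic_ou, n=5, seed=1)
        with pytest.raises(ValueError):
            fit(series, "ou")

    def test_unknown_family(self, isotropic_ou):
        series = _ou_series(isotropic_ou, n=30, seed=1)
        with pytest.raises(ValueError):
            fit(series, "var")


class TestLiberation:
    @staticmethod
    def _fit_lambda12(series, constraint_mode, warm=None, lo=-60.0):
        """1-D profile over lambda12 with the other parameters held fixed."""
        p = TestLiberation._truth
        bounds = [
            (p.lambda1, p.lambda1), (p.lambda2, p.lambda2),
            (max(lo, 0.0) if constraint_mode == "constrained" else lo, 60.0),
            (p.theta1, p.theta1), (p.theta2, p.theta2),
            (p.n1, p.n1), (p.n2, p.n2),
            (np.log10(p.diffusion), np.log10(p.diffusion)),
        ]
        return fit(
            series, "aim", bounds=bounds,
            de_config=DEConfig(population=6, generations=8, seed=3, polish_maxiter=100),
            constraint_mode=constraint_mode,
        )

    _truth = AIMParameters(3.0, 2.0, 0.0, 2.0, 2.2, 5.0, 5.0, diffusion=8e-4)

    def test_null_interaction_recovered_near_zero(self):
        series = generate_subject(self._truth, ProtocolSpec(days=14), seed=21)
        res = self._fit_lambda12(series, "liberated")
        assert abs(res.estimates.lambda12) < 1.5

    def test_inhibition_data_stays_positive(self):
        truth = AIMParameters(5.0, 5.0, 16.0, 1.5, 1.5, 1.8, 1.8, diffusion=2e-3)
        series = generate_subject(truth, ProtocolSpec(days=14), seed=22)
        bounds = [
            (truth.lambda1, truth.lambda1), (truth.lambda2, truth.lambda2),
            (-60.0, 60.0),
            (truth.theta1, truth.theta1), (truth.theta2, truth.theta2),
            (truth.n1, truth.n1), (truth.n2, truth.n2),
            (np.log10(truth.diffusion), np.log10(truth.diffusion)),
        ]
        res = fit(series, "aim", bounds=bounds,
                  de_config=DEConfig(population=6, generations=8, seed=4, polish_maxiter=100),
                  constraint_mode="liberated")
        assert res.estimates.lambda12 > 5.0

    def test_nested_model_inequality(self, smooth_unimodal):
        series = generate_subject(smooth_unimodal, ProtocolSpec(days=4), seed=23)
        de = DEConfig(population=8, generations=5, seed=6, polish_maxiter=100)
        constrained = fit(series, "aim", de_config=de)
        liberated = liberate_interaction(constrained, series, de_config=de)
        assert liberated.min_log_lik <= constrained.min_log_lik + 1e-3
        assert liberated.constraint_mode == "liberated"
        assert "lambda12_crossed_zero" in liberated.trace
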