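"""Likelihood and prior log-densities of the two mixture components."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import poisson

from baystmix.graphs import (build_adjacency, icar_logpdf,
                             temporal_path_adjacency)
from baystmix.model_core import (AreaSpecificParams, CommonParams, CountData,
                                 MixingFieldBaseline, MixingFieldProposed,
                                 area_specific_linpred, common_linpred,
                                 log_prior_baseline, log_prior_proposed,
                                 mixture_linpred, phi_field, poisson_loglik)


def _common(alpha0=0.0, eta=None, gamma=None, N=2, T=2, **kw):
    eta = np.zeros(N) if eta is None else np.asarray(eta, float)
    gamma = np.zeros(T) if gamma is None else np.asarray(gamma, float)
    defaults = dict(sigma2_eta=0.5, sigma2_v=0.5, sigma2_gamma=0.5)
    defaults.update(kw)
    return CommonParams(alpha0=alpha0, eta=eta, v=np.zeros_like(eta),
                        gamma=gamma, **defaults)


def _areasp(N=2, T=2, nu=None, kappa=None, **kw):
    nu = np.zeros(N) if nu is None else np.asarray(nu, float)
    kappa = np.zeros((N, T)) if kappa is None else np.asarray(kappa, float)
    defaults = dict(sigma2_kappa=np.full(N, 0.5), a_hyper=0.0, b_hyper=1.0)
    defaults.update(kw)
    return AreaSpecificParams(nu=nu, kappa=kappa, **defaults)


class TestLinearPredictors:
    def test_common_all_zero(self):
        np.testing.assert_array_equal(common_linpred(_common()), np.zeros((2, 2)))

    def test_common_elementwise(self):
        p = _common(alpha0=1.0, eta=[1.0, -1.0], gamma=[0.5, -0.5])
        np.testing.assert_allclose(common_linpred(p),
                                   [[2.5, 1.5], [0.5, -0.5]])

    def test_common_intercept_shift(self):
        p = _common(alpha0=0.3, eta=[0.1, 0.2], gamma=[0.0, -0.4])
        shifted = _common(alpha0=1.3, eta=[0.1, 0.2], gamma=[0.0, -0.4])
        np.testing.assert_allclose(common_linpred(shifted),
                                   common_linpred(p) + 1.0)

    def test_area_specific_elementwise(self):
        p = _areasp(nu=[1.0, 2.0], kappa=[[0.1, -0.1], [0.0, 0.0]])
        np.testing.assert_allclose(area_specific_linpred(p),
                                   [[1.1, 0.9], [2.0, 2.0]])

    def test_area_specific_flat_trend(self):
        p = _areasp(nu=[0.7, -0.2])
        out = area_specific_linpred(p)
        np.testing.assert_allclose(out, [[0.7, 0.7], [-0.2, -0.2]])


class TestMixtureLinpred:
    def test_selects_components_exactly(self, rng):
        muC = rng.standard_normal((3, 4))
        muAS = rng.standard_normal((3, 4))
        np.testing.assert_array_equal(
            mixture_linpred(np.ones((3, 4)), muC, muAS), muC)
        np.testing.assert_array_equal(
            mixture_linpred(np.zeros((3, 4)), muC, muAS), muAS)

    def test_mixed_matches_brute_force_loop(self, rng):
        muC = rng.standard_normal((3, 4))
        muAS = rng.standard_normal((3, 4))
        z = rng.integers(0, 2, size=(3, 4))
        got = mixture_linpred(z, muC, muAS)
        for i in range(3):
            for t in range(4):
                want = muC[i, t] if z[i, t] == 1 else muAS[i, t]
                assert got[i, t] == want

    def test_area_level_z_broadcasts_over_time(self, rng):
        muC = rng.standard_normal((3, 4))
        muAS = rng.standard_normal((3, 4))
        z_area = np.array([1, 0, 1])
        z_cell = np.repeat(z_area[:, None], 4, axis=1)
        np.testing.assert_array_equal(mixture_linpred(z_area, muC, muAS),
                                      mixture_linpred(z_cell, muC, muAS))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            mixture_linpred(np.full((2, 2), 0.5), np.zeros((2, 2)),
                            np.zeros((2, 2)))


class TestPoissonLoglik:
    def test_all_zero_counts(self):
        E = np.array([[1.0, 2.0], [3.0, 4.0]])
        data = CountData(Y=np.zeros((2, 2)), E=E)
        assert poisson_loglik(data, np.zeros((2, 2))) == pytest.approx(-E.sum())

    def test_single_cell_hand_value(self):
        data = CountData(Y=[[2]], E=[[1.0]])
        assert poisson_loglik(data, np.zeros((1, 1))) == pytest.approx(
            -1.0 - np.log(2.0))

    def test_matches_scipy_reference(self, tiny_counts, rng):
        log_mu = 0.2 * rng.standard_normal(tiny_counts.Y.shape)
        want = poisson.logpmf(tiny_counts.Y,
                              tiny_counts.E * np.exp(log_mu)).sum()
        assert poisson_loglik(tiny_counts, log_mu) == pytest.approx(
            want, abs=1e-10)

    def test_maximised_at_cellwise_mle(self, tiny_counts):
        mle = np.log(tiny_counts.Y / tiny_counts.E)
        best = poisson_loglik(tiny_counts, mle)
        assert best > poisson_loglik(tiny_counts, mle + 0.05)
        assert best > poisson_loglik(tiny_counts, mle - 0.05)

    def test_invalid_exposure_rejected(self):
        with pytest.raises(ValueError):
            CountData(Y=[[1]], E=[[0.0]])


class TestPhiField:
    def _mix(self, pi, delta, tau):
        N, T = len(pi), len(delta)
        return MixingFieldProposed(z=np.ones((N, T)), pi=np.asarray(pi, float),
                                   delta=np.asarray(delta, float), tau=tau,
                                   sigma2_pi=0.5, sigma2_delta=0.5)

    def test_zero_effects_give_tau(self):
        phi = phi_field(self._mix([0.0, 0.0], [0.0, 0.0, 0.0], 0.95))
        np.testing.assert_allclose(phi, 0.95)

    def test_logistic_rows(self):
        phi = phi_field(self._mix([1.0, -1.0], [0.0], 0.5))
        np.testing.assert_allclose(phi[:, 0], expit([1.0, -1.0]), rtol=1e-12)

    def test_large_pi_saturates(self):
        phi = phi_field(self._mix([40.0], [0.0], 0.5))
        assert phi[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_tau_rejected(self):
        with pytest.raises(ValueError):
            phi_field(self._mix([0.0], [0.0], 1.0))


class TestPriors:
    def setup_method(self):
        self.W = build_adjacency(2, [(0, 1)])
        self.Q = temporal_path_adjacency(2)

    def test_baseline_z_terms(self):
        common, areasp = _common(), _areasp()
        all1 = log_prior_baseline(common, areasp,
                                  MixingFieldBaseline(z=np.ones(2)),
                                  self.W, self.Q)
        all0 = log_prior_baseline(common, areasp,
                                  MixingFieldBaseline(z=np.zeros(2)),
                                  self.W, self.Q)
        assert all1 - all0 == pytest.approx(2 * (np.log(0.95) - np.log(0.05)))

    def test_proposed_bernoulli_term_matches_loop(self, rng):
        common, areasp = _common(N=3, T=4), _areasp(N=3, T=4)
        z = rng.integers(0, 2, size=(3, 4))
        mix = MixingFieldProposed(z=z, pi=rng.standard_normal(3) * 0.1,
                                  delta=np.zeros(4), tau=0.95,
                                  sigma2_pi=0.5, sigma2_delta=0.5)
        mix.pi -= mix.pi.mean()
        W3 = build_adjacency(3, [(0, 1), (1, 2)])
        Q4 = temporal_path_adjacency(4)
        base = log_prior_proposed(common, areasp, mix, W3, Q4)
        mix_all1 = MixingFieldProposed(z=np.ones((3, 4)), pi=mix.pi,
                                       delta=mix.delta, tau=mix.tau,
                                       sigma2_pi=0.5, sigma2_delta=0.5)
        base1 = log_prior_proposed(common, areasp, mix_all1, W3, Q4)
        phi = phi_field(mix)
        want = np.sum(z * np.log(phi) + (1 - z) * np.log(1 - phi))
        want1 = np.sum(np.log(phi))
        assert base - base1 == pytest.approx(want - want1, rel=1e-9)

    def test_tau_outside_support(self):
        common, areasp = _common(), _areasp()
        mix = MixingFieldProposed(z=np.ones((2, 2)), pi=np.zeros(2),
                                  delta=np.zeros(2), tau=0.85,
                                  sigma2_pi=0.5, sigma2_delta=0.5)
        assert log_prior_proposed(common, areasp, mix, self.W, self.Q) == -np.inf

    def test_baseline_total_is_sum_of_component_terms(self):
        """Independent re-evaluation of every prior factor."""
        from scipy.stats import halfnorm, norm

        common = _common(eta=[0.2, -0.1], gamma=[0.1, -0.1])
        common.v = np.array([0.15, -0.15])
        areasp = _areasp(nu=[0.3, -0.2], kappa=[[0.1, -0.1], [0.0, 0.0]],
                         a_hyper=0.2, b_hyper=0.8)
        mix = MixingFieldBaseline(z=np.array([1, 0]))
        got = log_prior_baseline(common, areasp, mix, self.W, self.Q)

        want = icar_logpdf(common.v, self.W, common.sigma2_v)
        want += norm.logpdf(common.eta, common.v,
                            np.sqrt(common.sigma2_eta)).sum()
        want += icar_logpdf(common.gamma, self.Q, common.sigma2_gamma)
        want += norm.logpdf(areasp.nu, 0, np.sqrt(1000.0)).sum()
        for i in range(2):
            want += icar_logpdf(areasp.kappa[i], self.Q,
                                areasp.sigma2_kappa[i])
        ls2 = np.log(areasp.sigma2_kappa)
        want += (norm.logpdf(ls2, 0.2, 0.8) - ls2).sum()
        want += norm.logpdf(0.2, 0, np.sqrt(1000.0))
        want += halfnorm.logpdf(0.8, scale=2.5)
        for s2 in (common.sigma2_eta, common.sigma2_v, common.sigma2_gamma):
            want += halfnorm.logpdf(s2, scale=1.0)
        want += np.log(0.95) + np.log(0.05)
        assert got == pytest.approx(want, rel=1e-9)

    def test_invalid_variance_rejected(self):
        common = _common(sigma2_eta=-1.0)
        with pytest.raises(ValueError):
            log_prior_baseline(common, _areasp(),
                               MixingFieldBaseline(z=np.ones(2)),
                               self.W, self.Q)
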