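"""Tests for the mean-field stack: simple MF, HMF, AAM and the LMFT."""

import math

import numpy as np
import pytest

from prefnet import (
    AAMModel,
    DegreeHistogram,
    FearFactor,
    LMFTState,
    aam_stationary_x,
    hmf_threshold,
    lmft_relax,
    lmft_rhs,
    mf_adaptive_lambda_of_x,
    mf_lambda_of_x,
    mf_onset_lambda,
    mf_threshold,
    mf_x_of_lambda,
    x_max,
)


def _bisect_lambda(x, mu, kappa, tol=1e-14):
    """Independent brute-force inversion of the stationarity relation."""
    g = lambda lam: mu * x - (1.0 - x) * (1.0 - (1.0 - lam) ** (kappa * x))
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestSimpleMF:
    def test_threshold_at_full_recovery(self):
        assert mf_threshold(1.0, 20.5) == pytest.approx(1.0)

    def test_threshold_closed_form_value(self):
        assert mf_threshold(0.1, 20.0) == pytest.approx(1.0 - 0.9**0.05, abs=1e-12)
        assert mf_threshold(0.1, 20.0) == pytest.approx(0.005255, abs=5e-6)

    def test_threshold_small_mu_limit(self):
        assert mf_threshold(1e-4, 20.5) == pytest.approx(1e-4 / 20.5, rel=1e-3)

    @pytest.mark.parametrize("mu", [0.05, 0.1, 0.3])
    @pytest.mark.parametrize("kappa", [10.5, 20.5])
    def test_inverse_matches_bisection(self, mu, kappa):
        for x in np.linspace(0.05, x_max(mu) - 0.05, 7):
            lam = mf_lambda_of_x(x, mu, kappa)
            assert lam == pytest.approx(_bisect_lambda(x, mu, kappa), abs=1e-10)

    def test_saturation_fixed_point(self):
        # at lam = 1 the stationary infected fraction is exactly 1/(1+mu)
        mu = 0.1
        assert mf_x_of_lambda(1.0, mu, 20.5) == x_max(mu)
        # the inverse curve approaches lam=1 (only logarithmically fast)
        assert mf_lambda_of_x(x_max(mu) - 1e-11, mu, 20.5) > 0.7

    def test_curve_continuous_at_onset(self):
        # the x->0 limit of lambda(x) approaches the threshold scale mu/kappa;
        # it matches the printed closed form only to O(mu/2) relative error
        mu, kappa = 0.1, 20.5
        lam_small = mf_lambda_of_x(1e-8, mu, kappa)
        assert lam_small == pytest.approx(mf_onset_lambda(mu, kappa), rel=1e-4)
        assert lam_small == pytest.approx(mf_threshold(mu, kappa), rel=mu)

    def test_infeasible_x_rejected(self):
        with pytest.raises(ValueError):
            mf_lambda_of_x(0.95, 0.1, 20.5)  # beyond 1/(1+mu)


class TestAdaptiveMF:
    def test_no_fear_is_identity(self):
        fear = FearFactor(kind="none", kappa0=20.5, kappa_inf=20.5)
        for x in (0.1, 0.3, 0.6):
            assert mf_adaptive_lambda_of_x(x, 0.1, fear) == mf_lambda_of_x(x, 0.1, 20.5)

    def test_reckless_jump_across_x_c(self):
        fear = FearFactor(kind="reckless", kappa0=20.5, kappa_inf=12.5, x_c=0.4)
        below = mf_adaptive_lambda_of_x(0.399, 0.1, fear)
        above = mf_adaptive_lambda_of_x(0.401, 0.1, fear)
        assert above > below * 1.3  # kappa drop demands a jump in lambda

    def test_vanishing_fear_factor_signals_infinity(self):
        fear = FearFactor(kind="nosophobic", kappa0=20.5, kappa_inf=1.0, severity_a=500.0)
        assert mf_adaptive_lambda_of_x(0.5, 0.1, fear) == math.inf


class TestHMF:
    def test_concentrated_degree_distribution_reduces_to_mf(self):
        counts = np.zeros(40, dtype=np.int64)
        counts[20] = 1000
        assert hmf_threshold(0.1, DegreeHistogram(counts)) == pytest.approx(
            mf_threshold(0.1, 20.0), abs=1e-12
        )

    def test_broader_distribution_lowers_threshold(self):
        narrow = np.zeros(40, dtype=np.int64)
        narrow[20] = 1000
        broad = np.zeros(40, dtype=np.int64)
        broad[[10, 30]] = 500  # same <k>, larger <k^2>
        assert hmf_threshold(0.1, DegreeHistogram(broad)) < hmf_threshold(0.1, DegreeHistogram(narrow))


class TestAAM:
    def test_no_transmission_gives_empty_state(self):
        model = AAMModel.uniform(50, 10.0)
        x, rho = aam_stationary_x(model, mu=0.1, lam=0.0)
        assert x == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(rho, 0.0, atol=1e-6)

    def test_two_node_toy_solved_by_hand(self):
        # abar = [[0,1],[1,0]]: the fixed point solves mu = lam (1 - rho),
        # i.e. rho* = 1 - mu/lam
        model = AAMModel(np.array([[0.0, 1.0], [1.0, 0.0]]))
        x, rho = aam_stationary_x(model, mu=0.1, lam=0.4, tol=1e-13)
        assert np.allclose(rho, 1.0 - 0.1 / 0.4, atol=1e-6)
        assert x == pytest.approx(0.75, abs=1e-6)

    def test_uniform_annealed_matrix_tracks_mf_near_threshold(self):
        mu, kappa, n = 0.1, 20.5, 400
        model = AAMModel.uniform(n, kappa)
        lam = 1.6 * mf_onset_lambda(mu, kappa)
        x_aam, _ = aam_stationary_x(model, mu, lam, tol=1e-11)
        x_mf = mf_x_of_lambda(lam, mu, kappa)
        assert x_aam == pytest.approx(x_mf, abs=0.02)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            AAMModel(np.array([[0.0, 1.0], [0.5, 0.0]]))


class TestLMFT:
    def test_healthy_state_is_an_exact_fixed_point(self):
        fear = FearFactor(kind="typical", kappa0=20.5, kappa_inf=12.5, x_c=0.4)
        state = LMFTState(x=0.0, l_ss=20.5 / 2.0, l_si=0.0, l_ii=0.0)
        rhs = lmft_rhs(state, mu=0.1, lam=0.02, w=1.0, sigma=5.0, fear=fear, beta=1.0)
        assert np.allclose(rhs, 0.0, atol=1e-12)

    def test_unbiased_mixing_state_reproduces_simple_mf(self):
        """At sigma=0 the random-mixing composition at the MF fixed point is
        itself stationary, for any adaptation rate."""
        mu, kappa, lam = 0.1, 20.5, 0.012
        fear = FearFactor(kind="none", kappa0=kappa, kappa_inf=kappa)
        x_star = mf_x_of_lambda(lam, mu, kappa)
        state = LMFTState.mixing(x_star, kappa)
        for w in (0.5, 1.0, 10.0):
            rhs = lmft_rhs(state, mu, lam, w, 0.0, fear, beta=1.0)
            assert np.allclose(rhs, 0.0, atol=1e-9)

    def test_relaxation_finds_the_mf_fixed_point(self):
        mu, kappa, lam = 0.1, 20.5, 0.012
        fear = FearFactor(kind="none", kappa0=kappa, kappa_inf=kappa)
        fp = lmft_relax(LMFTState.mixing(1e-3, kappa), mu, lam, 10.0, 0.0, fear, t_max=6000.0)
        assert fp.converged and fp.stable
        assert fp.state.x == pytest.approx(mf_x_of_lambda(lam, mu, kappa), abs=1e-6)

    def test_slow_adaptation_limit_reduces_to_mf(self):
        """With the adaptation flux nearly frozen the selective bias cannot
        reorganize links: the stationary x approaches the simple MF value."""
        mu, kappa, lam = 0.1, 20.5, 0.012
        fear = FearFactor(kind="none", kappa0=kappa, kappa_inf=kappa)
        fp = lmft_relax(LMFTState.mixing(0.2, kappa), mu, lam, 5000.0, 3.0, fear, t_max=6000.0)
        assert fp.converged
        assert fp.state.x == pytest.approx(mf_x_of_lambda(lam, mu, kappa), abs=0.02)

    def test_selective_bias_suppresses_prevalence(self):
        mu, kappa, lam = 0.1, 20.5, 0.008
        fear = FearFactor(kind="none", kappa0=kappa, kappa_inf=kappa)
        fp0 = lmft_relax(LMFTState.mixing(0.3, kappa), mu, lam, 1.0, 0.0, fear, t_max=6000.0)
        fp5 = lmft_relax(LMFTState.mixing(0.3, kappa), mu, lam, 1.0, 5.0, fear, t_max=6000.0)
        assert fp5.state.x < fp0.state.x - 0.05
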