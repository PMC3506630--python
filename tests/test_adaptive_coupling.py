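"""Tests for fear factors and blind/selective adaptive link updates."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prefnet import (
    EpidemicState,
    FearFactor,
    KernelRng,
    NetworkState,
    SimulationConfig,
    SISRates,
    preferred_degree,
    run_coupled,
    selective_add_target_prob,
    selective_cut_target_prob,
    selective_link_update,
)


class TestPreferredDegree:
    @pytest.mark.parametrize("kind", ["none", "reckless", "typical", "nosophobic"])
    def test_no_fear_at_zero_prevalence(self, kind):
        fear = FearFactor(kind=kind, kappa0=20.5, kappa_inf=12.5, x_c=0.4)
        assert preferred_degree(fear, 0.0) == pytest.approx(20.5)

    def test_reckless_heaviside_drop(self):
        fear = FearFactor(kind="reckless", kappa0=20.5, kappa_inf=12.5, x_c=0.4)
        assert preferred_degree(fear, 0.399) == pytest.approx(20.5)
        assert preferred_degree(fear, 0.401) == pytest.approx(12.5)

    def test_typical_linear_midpoint(self, typical_fear):
        mid = preferred_degree(typical_fear, typical_fear.x_c / 2.0)
        assert mid == pytest.approx((20.5 + 12.5) / 2.0)

    def test_typical_clamped_beyond_x_c(self, typical_fear):
        assert preferred_degree(typical_fear, 0.9) == pytest.approx(12.5)

    def test_nosophobic_exponential(self):
        fear = FearFactor(kind="nosophobic", kappa0=20.5, kappa_inf=1.0, severity_a=25.0)
        assert preferred_degree(fear, 0.1) == pytest.approx(20.5 * math.exp(-2.5))

    def test_out_of_range_prevalence_rejected(self, typical_fear):
        with pytest.raises(ValueError):
            preferred_degree(typical_fear, 1.5)

    @given(
        x1=st.floats(0.0, 1.0),
        x2=st.floats(0.0, 1.0),
        kind=st.sampled_from(["reckless", "typical", "nosophobic"]),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_and_bounded(self, x1, x2, kind):
        fear = FearFactor(kind=kind, kappa0=20.5, kappa_inf=10.5, x_c=0.4, severity_a=25.0)
        lo, hi = sorted((x1, x2))
        k_lo, k_hi = preferred_degree(fear, lo), preferred_degree(fear, hi)
        assert k_hi <= k_lo + 1e-9  # fear never relaxes as prevalence grows
        assert 0.0 < k_hi <= 20.5 + 1e-9
        if kind != "nosophobic":
            assert k_hi >= 10.5 - 1e-9


class TestSelectiveRoutingProbabilities:
    def test_cut_without_infected_contacts(self):
        assert selective_cut_target_prob(5.0, 0, 4) == 0.0

    def test_unbiased_cut_is_degree_proportional(self):
        assert selective_cut_target_prob(0.0, 2, 3) == pytest.approx(0.4)

    def test_large_bias_cut_targets_infected(self):
        assert selective_cut_target_prob(1e12, 1, 9) == pytest.approx(1.0, abs=1e-10)

    def test_add_with_no_infected_in_population(self):
        assert selective_add_target_prob(3.0, 10, 0) == 1.0

    def test_unbiased_add_is_population_proportional(self):
        assert selective_add_target_prob(0.0, 30, 70) == pytest.approx(0.3)

    def test_large_bias_add_targets_susceptibles(self):
        assert selective_add_target_prob(1e12, 1, 99) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            selective_cut_target_prob(1.0, 0, 0)
        with pytest.raises(ValueError):
            selective_add_target_prob(1.0, 0, 0)

    @given(
        sigma1=st.floats(0.0, 50.0),
        dsigma=st.floats(0.1, 50.0),
        k_i=st.integers(1, 30),
        k_s=st.integers(1, 30),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_in_bias_and_complementary(self, sigma1, dsigma, k_i, k_s):
        p1 = selective_cut_target_prob(sigma1, k_i, k_s)
        p2 = selective_cut_target_prob(sigma1 + dsigma, k_i, k_s)
        assert p2 > p1  # strictly increasing when 0 < k_i < k
        assert 0.0 <= p1 <= 1.0
        q = selective_add_target_prob(sigma1, k_s, k_i)
        assert 0.0 <= q <= 1.0
        # the two routed outcomes are complementary by construction
        assert p1 + ((1.0 + sigma1) * k_i / ((1.0 + sigma1) * k_i + k_s) - p1) == p1


def _cfg(**kw):
    defaults = dict(
        n=300,
        rates=SISRates(mu=0.1, lam=0.012),
        kappa0=10.5,
        beta=math.inf,
        w=5.0,
        x0=0.1,
        net_burn_in_mcs=200,
        burn_in_mcs=300,
        sample_mcs=300,
        interval=10,
        seed=77,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestBlindAdaptation:
    def test_absent_fear_is_bitwise_nonadaptive(self):
        """fear='none' must follow exactly the same trajectory as no fear at
        all under a shared seed (f == 1 changes nothing)."""
        rec_none = run_coupled(_cfg(fear=None))
        rec_f1 = run_coupled(_cfg(fear=FearFactor(kind="none", kappa0=10.5, kappa_inf=10.5)))
        assert np.array_equal(rec_none.x, rec_f1.x)
        assert rec_none.final_network.edges() == rec_f1.final_network.edges()

    def test_reckless_fear_reduces_mean_degree_above_x_c(self):
        fear = FearFactor(kind="reckless", kappa0=10.5, kappa_inf=4.5, x_c=0.2)
        rec = run_coupled(_cfg(fear=fear, rates=SISRates(mu=0.1, lam=0.05), w=2.0))
        assert rec.x.mean() > 0.2  # epidemic strong enough to trigger the fear
        mean_deg = rec.final_network.degree.mean()
        assert mean_deg < 7.0  # network recentred towards kappa_inf, not kappa0

    def test_kappa_current_tracks_fear_factor(self, typical_fear):
        cfg = _cfg(
            kappa0=20.5,
            fear=typical_fear,
            rates=SISRates(mu=0.1, lam=0.02),
        )
        rec = run_coupled(cfg)
        expected = [preferred_degree(typical_fear, x) for x in rec.x]
        assert np.allclose(rec.kappa_t, expected)


class TestSelectiveAdaptation:
    def test_all_susceptible_population_keeps_network_stationary(self):
        """With no infection the selective rules reduce to plain preferred-
        degree dynamics: mean degree stays at kappa."""
        net = NetworkState(200)
        epi = EpidemicState(state=np.zeros(200, dtype=np.int8), n_infected=0, immortal_enabled=False)
        fear = FearFactor(kind="typical", kappa0=8.5, kappa_inf=4.5, x_c=0.4)
        rng = KernelRng(5, stream=1)
        for sweep in range(400):
            for _ in range(200):
                selective_link_update(net, epi, rng.integers(200), fear, math.inf, 3.0, rng)
        assert abs(net.degree.mean() - 8.5) / 8.5 < 0.05
        net.validate()

    def test_zero_bias_matches_blind_statistically(self):
        """sigma=0 removes all state dependence: matched ensembles of <x>
        agree within two standard errors."""
        from prefnet import ensemble_mean_x

        fear = FearFactor(kind="typical", kappa0=10.5, kappa_inf=6.5, x_c=0.4)
        base = _cfg(fear=fear, rates=SISRates(mu=0.1, lam=0.02), w=2.0)
        m_sel, se_sel, _ = ensemble_mean_x(replace(base, selective=True, sigma=0.0), 6)
        m_bl, se_bl, _ = ensemble_mean_x(replace(base, selective=False), 6, base_seed=base.seed + 555)
        assert abs(m_sel - m_bl) < 2.0 * math.hypot(se_sel, se_bl) + 1e-9

    def test_strong_bias_interconnects_the_infected(self):
        """Above threshold with strong bias the infected end up more strongly
        interconnected than with the susceptibles: positive S/I modularity."""
        from prefnet.observables import modularity_from_link_counts

        fear = FearFactor(kind="typical", kappa0=10.5, kappa_inf=6.5, x_c=0.5)
        cfg = _cfg(fear=fear, selective=True, sigma=10.0, rates=SISRates(mu=0.1, lam=0.03), w=1.0)
        rec = run_coupled(cfg)
        qs = [
            modularity_from_link_counts(a, b, c)
            for a, b, c in zip(rec.n_ss, rec.n_si, rec.n_ii)
        ]
        assert 0.05 < rec.x.mean() < 0.95
        assert np.mean(qs) > 0.02

    def test_selective_moves_change_exactly_one_edge(self):
        net = NetworkState(50)
        rng = KernelRng(11, stream=1)
        sig = np.zeros(50, dtype=np.int8)
        sig[:10] = 1
        epi = EpidemicState(state=sig, n_infected=10)
        fear = FearFactor(kind="none", kappa0=6.5, kappa_inf=6.5)
        for _ in range(500):
            before = net.n_edges
            selective_link_update(net, epi, rng.integers(50), fear, math.inf, 4.0, rng)
            assert abs(net.n_edges - before) <= 1
        net.validate()
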