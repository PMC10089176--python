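import itertools
import math

import numpy as np
import pytest
from scipy import stats

from phylodisp.ctmc import n_routes
from phylodisp.priors import (
    EventCountPrior,
    count_configurations,
    delta_count_pmf,
    is_irreducible,
    log_prior_delta,
    log_prior_mu,
    log_prior_relative_rates,
    prior_event_count_distribution,
    prior_route_inclusion_probability,
    resolve_prior_config,
    sample_from_prior,
    _connected_graph_count,
    _enumerate_connected_count,
)


class TestResolve:
    def test_default_symmetric_lambda_is_ln2_with_offset(self):
        for k in (3, 5, 12):
            cfg = resolve_prior_config(k=k, T=10.0, symmetric=True)
            assert cfg.lam == pytest.approx(math.log(2))
            assert cfg.offset == k - 1

    def test_default_asymmetric_mean_is_k_minus_1(self):
        cfg = resolve_prior_config(k=7, T=1.0, symmetric=False)
        assert cfg.lam == pytest.approx(6.0)
        assert cfg.offset == 0

    def test_alternative_asymmetric_half_of_possible_routes(self):
        cfg = resolve_prior_config(routes_prior="alternative", k=5, T=1.0,
                                   symmetric=False)
        assert cfg.lam == pytest.approx(10.0)  # K = 20

    def test_alternative_symmetric_centres_on_half_max(self):
        cfg = resolve_prior_config(routes_prior="alternative", k=8, T=1.0,
                                   symmetric=True)
        # K = 28; expected Delta = offset + lam = 7 + (14 - 7) = 14 = K/2
        assert cfg.offset + cfg.lam == pytest.approx(14.0)

    def test_alternative_symmetric_floor_for_tiny_k(self):
        cfg = resolve_prior_config(routes_prior="alternative", k=3, T=1.0,
                                   symmetric=True)
        assert cfg.lam == pytest.approx(math.log(2))  # K/2 - (k-1) < 0

    def test_default_rate_prior_uses_tree_length(self):
        cfg = resolve_prior_config(k=3, T=42.0, symmetric=True)
        assert cfg.rate_shape == 0.5
        assert cfg.rate_rate == 42.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            resolve_prior_config(k=1, T=1.0, symmetric=True)
        with pytest.raises(ValueError):
            resolve_prior_config(k=3, T=0.0, symmetric=True)


class TestConfigurationCounting:
    @pytest.mark.parametrize("k,delta,expected", [
        (3, 2, 3),    # the three two-route models
        (3, 3, 1),    # complete graph
        (4, 3, 16),   # the 16 spanning trees of K4
        (4, 6, 1),
        (3, 1, 0),    # below the connectivity minimum
    ])
    def test_symmetric_irreducible_counts(self, k, delta, expected):
        assert count_configurations(k, delta, True, True) == expected

    def test_without_irreducibility_is_binomial(self):
        assert count_configurations(4, 3, True, False) == math.comb(6, 3)
        assert count_configurations(3, 2, False, False) == math.comb(6, 2)

    def test_recurrence_agrees_with_enumeration(self):
        for k in (3, 4, 5):
            K = k * (k - 1) // 2
            for d in range(K + 1):
                assert _connected_graph_count(k, d) == _enumerate_connected_count(k, d)

    def test_out_of_range_delta(self):
        with pytest.raises(ValueError):
            count_configurations(3, 4, True, True)

    def test_irreducibility_predicate(self):
        # k=4 pairs: (01)(02)(03)(12)(13)(23); a path 0-1-2-3 is connected
        assert is_irreducible(np.array([1, 0, 0, 1, 0, 1]), 4, True)
        # two disjoint edges are not
        assert not is_irreducible(np.array([1, 0, 0, 0, 0, 1]), 4, True)
        # directed cycle 0->1->2->0 is strongly connected
        delta = np.zeros(6, int)
        # ordered pairs for k=3: (01)(02)(10)(12)(20)(21)
        delta[[0, 3, 4]] = 1
        assert is_irreducible(delta, 3, False)
        delta2 = np.zeros(6, int)
        delta2[[0, 1]] = 1  # 0->1, 0->2 only: nothing returns to 0
        assert not is_irreducible(delta2, 3, False)


class TestDeltaPrior:
    def test_below_minimum_is_impossible(self):
        cfg = resolve_prior_config(k=3, T=1.0, symmetric=True)
        assert log_prior_delta(np.array([1, 0, 0]), cfg) == float("-inf")

    def test_hand_computed_two_route_probability(self):
        # k=3 default: renormalized offset Poisson over Delta in {2, 3},
        # divided by the 3 equiprobable two-route models
        cfg = resolve_prior_config(k=3, T=1.0, symmetric=True)
        z = stats.poisson.pmf(0, cfg.lam) + stats.poisson.pmf(1, cfg.lam)
        expected = math.log(stats.poisson.pmf(0, cfg.lam) / z / 3)
        assert log_prior_delta(np.array([1, 1, 0]), cfg) == pytest.approx(expected)

    @pytest.mark.parametrize("symmetric,k", [(True, 3), (True, 4), (False, 3)])
    @pytest.mark.parametrize("style", ["per-delta-count", "per-configuration"])
    def test_normalization_over_all_configurations(self, symmetric, k, style):
        cfg = resolve_prior_config(k=k, T=1.0, symmetric=symmetric,
                                   delta_prior_style=style)
        K = n_routes(k, symmetric)
        total = 0.0
        for bits in itertools.product([0, 1], repeat=K):
            lp = log_prior_delta(np.array(bits), cfg)
            if lp > float("-inf"):
                total += math.exp(lp)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_delta_marginal_matches_renormalized_offset_poisson(self):
        cfg = resolve_prior_config(k=4, T=1.0, symmetric=True)
        support, pmf = delta_count_pmf(cfg)
        # direct summation over all configurations
        K = 6
        totals = {int(d): 0.0 for d in support}
        for bits in itertools.product([0, 1], repeat=K):
            lp = log_prior_delta(np.array(bits), cfg)
            if lp > float("-inf"):
                totals[sum(bits)] += math.exp(lp)
        for d, p in zip(support, pmf):
            assert totals[int(d)] == pytest.approx(p, abs=1e-12)

    def test_unknown_style_rejected(self):
        cfg = resolve_prior_config(k=3, T=1.0, symmetric=True,
                                   delta_prior_style="nope")
        with pytest.raises(ValueError):
            delta_count_pmf(cfg)


class TestRouteInclusionProbability:
    @pytest.mark.parametrize("symmetric,k", [(True, 3), (True, 4), (False, 3)])
    def test_equals_enumeration_average(self, symmetric, k):
        cfg = resolve_prior_config(k=k, T=1.0, symmetric=symmetric)
        K = n_routes(k, symmetric)
        p_first = 0.0
        for bits in itertools.product([0, 1], repeat=K):
            lp = log_prior_delta(np.array(bits), cfg)
            if lp > float("-inf") and bits[0] == 1:
                p_first += math.exp(lp)
        assert prior_route_inclusion_probability(cfg) == pytest.approx(p_first, abs=1e-12)

    def test_two_term_sum_for_k3_default(self):
        cfg = resolve_prior_config(k=3, T=1.0, symmetric=True)
        support, pmf = delta_count_pmf(cfg)
        expected = float(np.sum(pmf * support) / 3)
        assert prior_route_inclusion_probability(cfg) == pytest.approx(expected)

    def test_alternative_asymmetric_is_about_half(self):
        cfg = resolve_prior_config(routes_prior="alternative", k=5, T=1.0,
                                   symmetric=False)
        assert prior_route_inclusion_probability(cfg) == pytest.approx(0.5, abs=0.01)

    def test_default_symmetric_drops_with_k(self):
        probs = [prior_route_inclusion_probability(
            resolve_prior_config(k=k, T=1.0, symmetric=True))
            for k in range(3, 21)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_alternative_stays_flat_relative_to_default(self):
        # at k = 15 the default inclusion probability is tiny, the
        # alternative stays near 1/2
        d = prior_route_inclusion_probability(
            resolve_prior_config(k=15, T=1.0, symmetric=True))
        a = prior_route_inclusion_probability(
            resolve_prior_config(routes_prior="alternative", k=15, T=1.0,
                                 symmetric=True))
        assert d < 0.15
        assert 0.4 < a < 0.6


class TestRatePrior:
    def test_default_is_gamma_kernel(self):
        cfg = resolve_prior_config(k=3, T=10.0, symmetric=True)
        mu = 0.07
        expected = stats.gamma.logpdf(mu, a=0.5, scale=1 / 10.0)
        assert log_prior_mu(mu, None, cfg) == pytest.approx(expected)

    def test_default_prior_mean_is_half_over_T(self):
        for T in (1.0, 10.0, 100.0):
            cfg = resolve_prior_config(k=3, T=T, symmetric=True)
            rng = np.random.default_rng(0)
            draws = np.array([sample_from_prior(cfg, rng).mu for _ in range(4000)])
            assert draws.mean() == pytest.approx(0.5 / T, rel=0.1)

    def test_alternative_total_expectation(self):
        # E[mu] = E[m] = shape/rate = 1 by the law of total expectation
        cfg = resolve_prior_config(k=3, T=5.0, rate_prior="alternative",
                                   symmetric=True)
        rng = np.random.default_rng(1)
        mus = np.array([sample_from_prior(cfg, rng).mu for _ in range(60_000)])
        # heavy-tailed (K-distribution): generous MC tolerance
        assert mus.mean() == pytest.approx(1.0, abs=0.08)

    def test_alternative_requires_hyper_mean(self):
        cfg = resolve_prior_config(k=3, T=5.0, rate_prior="alternative",
                                   symmetric=True)
        with pytest.raises(ValueError):
            log_prior_mu(0.5, None, cfg)

    def test_nonpositive_rate_has_zero_density(self):
        cfg = resolve_prior_config(k=3, T=5.0, symmetric=True)
        assert log_prior_mu(-1.0, None, cfg) == float("-inf")


class TestEventCountPrior:
    def test_default_mean_half_for_all_tree_lengths(self):
        for T in (1.0, 10.0, 100.0):
            cfg = resolve_prior_config(k=3, T=T, symmetric=True)
            ecp = prior_event_count_distribution(cfg, T=T)
            assert ecp.mean == pytest.approx(0.5, abs=1e-9)

    def test_default_95_interval_upper_is_three(self):
        for T in (1.0, 10.0, 100.0):
            cfg = resolve_prior_config(k=3, T=T, symmetric=True)
            assert prior_event_count_distribution(cfg, T=T).quantile(0.975) == 3

    def test_default_mass_at_zero_is_sqrt_half(self):
        cfg = resolve_prior_config(k=3, T=7.0, symmetric=True)
        ecp = prior_event_count_distribution(cfg, T=7.0)
        # Gamma-Poisson mixture integral at n=0:
        # \int Pois(0; mu T) Gamma(mu; 1/2, T) dmu = (1/2)^(1/2)
        assert ecp.pmf[0] == pytest.approx(2 ** -0.5, abs=1e-12)

    def test_alternative_mean_grows_with_tree_length(self):
        cfg = resolve_prior_config(k=3, T=1.0, rate_prior="alternative",
                                   symmetric=True)
        means = []
        for T in (1.0, 5.0, 25.0):
            ecp = prior_event_count_distribution(cfg, T=T, n_max=600, n_mc=4_000)
            means.append(ecp.mean)
            assert np.all(ecp.mc_se >= 0)
        assert means[0] < means[1] < means[2]


class TestRelativeRatePrior:
    def test_unit_rates(self):
        cfg = resolve_prior_config(k=3, T=1.0, symmetric=True)
        assert log_prior_relative_rates(np.ones(3), cfg) == pytest.approx(-3.0)
        assert log_prior_relative_rates(np.array([0.5]), cfg) == pytest.approx(-0.5)

    def test_prior_sampler_matches_density(self):
        cfg = resolve_prior_config(k=4, T=1.0, symmetric=True)
        rng = np.random.default_rng(2)
        draws = np.concatenate([sample_from_prior(cfg, rng).r for _ in range(500)])
        ks = stats.kstest(draws, "expon")
        assert ks.pvalue > 0.01


class TestPriorSampler:
    def test_delta_draws_follow_marginal(self):
        cfg = resolve_prior_config(k=4, T=1.0, symmetric=True)
        rng = np.random.default_rng(3)
        support, pmf = delta_count_pmf(cfg)
        draws = np.array([sample_from_prior(cfg, rng).n_active for _ in range(4000)])
        freqs = np.array([(draws == d).mean() for d in support])
        assert np.abs(freqs - pmf).sum() / 2 < 0.03  # total variation
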