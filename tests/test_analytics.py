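"""Closed-form analytics: strength dynamics, strength/degree laws,
connection probabilities, and the permutation-averaged marginal."""

import numpy as np
import pytest
from scipy import stats

from hvnet.growth import HiddenVariableSpec, grow
from hvnet import analytics as an


class TestMeanStrength:
    def test_initial_condition(self):
        assert an.mean_strength(2.0, 5.0, 5.0, kappa=3.0) == 3.0

    def test_log_e_ratio(self):
        assert np.isclose(an.mean_strength(2.0, 1.0, np.e), 2.0)

    def test_ordering_error(self):
        with pytest.raises(ValueError):
            an.mean_strength(1.0, 10.0, 5.0)

    def test_monte_carlo_tracked_node(self):
        """Simulated strength of a tracked node matches theta ln(t/t_i) + kappa."""
        theta = np.full(2000, 1.0)
        theta[9] = 2.0  # tracked node arrives at t_i = 10
        vals = []
        for seed in range(200):
            g = grow(theta, 2000, seed)
            vals.append(g.strengths()[9] - g.kappa[9])
        vals = np.asarray(vals, dtype=float)
        pred = an.mean_strength(2.0, 10.0, 2000.0)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - pred) < 3 * se


class TestMeanStrengthOverArrivals:
    def test_zero_theta(self):
        assert an.mean_strength_over_arrivals(0.0, 100.0) == 0.0

    def test_large_t_limit_is_twice_theta(self):
        assert abs(an.mean_strength_over_arrivals(1.0, 1e4) - 2.0) < 2e-3

    def test_domain_error(self):
        with pytest.raises(ValueError):
            an.mean_strength_over_arrivals(1.0, 1.0)

    def test_simulation_mean_ratio(self):
        """One sparse run: mean over nodes of s_i/theta_i within 5% of 2."""
        n = 10_000
        spec = HiddenVariableSpec(gamma=2.5, theta_min=1.0, theta_max=np.sqrt(n))
        g = grow(spec, n, 21)
        ratio = (g.strengths() / g.theta).mean()
        assert abs(ratio - 2.0) < 0.1


class TestMasterEquation:
    def test_zero_theta_point_mass(self):
        out = an.master_equation_iterate([0.0], [1.0], 1000, 10)
        assert np.isclose(out[0, 0], 1.0) and np.allclose(out[0, 1:], 0.0)

    def test_converges_to_closed_form(self):
        """The rate-equation iteration is the oracle for the closed form."""
        out = an.master_equation_iterate([1.0], [1.0], 20_000, 120)
        closed = an.strength_pmf_conditional_vector(1.0, 120)
        assert np.abs(out[0] - closed).max() < 1e-3

    def test_mass_conservation(self):
        out = an.master_equation_iterate([0.5, 2.0], [0.4, 0.6], 5000, 150)
        assert np.isclose(out.sum(), 1.0, atol=1e-6)


class TestStrengthPmf:
    def test_zero_theta_degenerate(self):
        assert an.strength_pmf_conditional(0.0, 0) == 1.0
        assert an.strength_pmf_conditional(0.0, 3) == 0.0

    @pytest.mark.parametrize("theta", [0.3, 1.0, 4.0])
    def test_normalization(self, theta):
        pmf = an.strength_pmf_conditional_vector(theta, 400)
        assert abs(pmf.sum() - 1.0) < 1e-6

    def test_s_zero_value(self):
        """P(s=0 | theta=1) is the kappa=0 term: e^-1 / 2."""
        assert np.isclose(an.strength_pmf_conditional(1.0, 0), np.exp(-1) / 2)

    def test_vector_matches_direct_sum(self):
        vec = an.strength_pmf_conditional_vector(2.5, 50)
        direct = [an.strength_pmf_conditional(2.5, s) for s in range(51)]
        assert np.allclose(vec, direct, atol=1e-12)

    def test_degenerate_spec_marginal_equals_conditional(self):
        spec = HiddenVariableSpec(theta_min=2.0, theta_max=2.0)
        dist = an.strength_pmf_marginal(spec, 60)
        assert np.allclose(dist.marginal,
                           an.strength_pmf_conditional_vector(2.0, 60))

    def test_tail_exponent_inherited(self):
        """Strength marginal inherits the hidden-variable exponent."""
        spec = HiddenVariableSpec(gamma=2.5, theta_min=1.0, theta_max=1000.0)
        assert abs(an.tail_exponent_check(spec, s_min=10, s_max=1000) - 2.5) < 0.1

    def test_tail_exponent_gamma_below_two(self):
        spec = HiddenVariableSpec(gamma=1.5, theta_min=1.0, theta_max=1000.0)
        assert abs(an.tail_exponent_check(spec, s_min=10, s_max=1000) - 1.5) < 0.15


class TestConnectionProbability:
    def test_zero_theta_gives_zero(self):
        model = an.ConnectionModel([0.0, 1.0, 2.0])
        assert an.connection_probability(1, 3, model) == 0.0

    def test_asymptotic_closed_form(self):
        theta = np.ones(100)
        model = an.ConnectionModel(theta)
        p = an.connection_probability(1, 100, model, mode="asymptotic")
        assert np.isclose(p, 1 - np.exp(-0.01))

    def test_self_pair_rejected(self):
        model = an.ConnectionModel([1.0, 1.0])
        with pytest.raises(ValueError):
            an.connection_probability(2, 2, model)

    def test_symmetric_in_argument_order(self):
        model = an.ConnectionModel([1.0, 2.0, 3.0, 0.5])
        assert (an.connection_probability(2, 4, model)
                == an.connection_probability(4, 2, model))

    def test_monte_carlo_link_frequency(self):
        """Empirical link rate of a tracked pair matches exact_sum mode."""
        rng = np.random.default_rng(4)
        theta = np.sort(rng.uniform(0.5, 3.0, 50))[::-1].copy()
        model = an.ConnectionModel(theta)
        i, j = 5, 30
        p = an.connection_probability(i, j, model, mode="exact_sum")
        hits = sum((i, j) in grow(theta, 50, seed).weights
                   for seed in range(10_000))
        sigma = np.sqrt(p * (1 - p) * 10_000)
        assert abs(hits - p * 10_000) < 3 * sigma


class TestExpectedDegree:
    def test_zero_theta_node(self):
        model = an.ConnectionModel([0.0, 1.0, 1.0])
        assert an.expected_degree(1, model) == 0.0
        assert an.degree_pmf_node(0.0, 0) == 1.0

    def test_poisson_pmf_normalized(self):
        k = np.arange(200)
        assert np.isclose(an.degree_pmf_node(7.3, k).sum(), 1.0)

    def test_degree_histogram_poisson_gof(self):
        """Tracked-node degree over sparse runs is Poisson(kbar)."""
        n = 200
        rng = np.random.default_rng(2024)
        from hvnet.growth import sample_theta

        theta = sample_theta(
            HiddenVariableSpec(gamma=2.5, theta_min=1.0, theta_max=np.sqrt(n)),
            n, rng)
        tracked = 20
        kbar = an.expected_degree(tracked, an.ConnectionModel(theta))
        degs = np.array([grow(theta, n, 5000 + r).degrees()[tracked - 1]
                         for r in range(800)])
        kmax = degs.max()
        obs = np.bincount(degs, minlength=kmax + 2).astype(float)
        exp = stats.poisson.pmf(np.arange(kmax + 2), kbar) * len(degs)
        exp[-1] = len(degs) - exp[:-1].sum()
        keep = exp >= 5
        obs_k = np.append(obs[keep], obs[~keep].sum())
        exp_k = np.append(exp[keep], exp[~keep].sum())
        chi2 = np.sum((obs_k - exp_k) ** 2 / np.maximum(exp_k, 1e-12))
        assert stats.chi2.sf(chi2, len(obs_k) - 1) > 0.01


class TestDegreeDistributionEnsemble:
    def test_zero_spec_all_isolated(self):
        spec = HiddenVariableSpec(family="explicit", values=[0.0] * 50)
        curve = an.degree_distribution_ensemble(spec, 50, mode="analytic", k_max=10)
        assert np.isclose(curve.pk[0], 1.0)

    def test_analytic_matches_simulated(self):
        """Analytic Poisson mixture tracks the simulated histogram."""
        n = 3000
        spec = HiddenVariableSpec(gamma=2.5, theta_min=1.0, theta_max=np.sqrt(n))
        sim = an.degree_distribution_ensemble(spec, n, mode="simulated",
                                              rng=8, n_runs=20, k_max=80)
        ana = an.degree_distribution_ensemble(spec, n, mode="analytic", k_max=80)
        counts = sim.pk * (20 * n)
        for k in range(30):
            mc_sigma = np.sqrt(max(counts[k], 1.0)) / (20 * n)
            assert abs(sim.pk[k] - ana.pk[k]) < 5 * mc_sigma + 2e-3


class TestPermutationMarginal:
    def test_zero_theta(self):
        assert an.permutation_marginal(0.0, 1.0, 100, 1.0, "integral") == 0.0
        assert an.permutation_marginal(0.0, 1.0, 100, 1.0, "asymptotic") == 0.0

    def test_prefactor_two(self):
        """Quadrature over arrival times doubles the naive 1/N marginal."""
        val = an.permutation_marginal(1.0, 1.0, 10**6, 1.0, "integral")
        assert abs(val / (1.0 / 10**6) - 2.0) < 0.02

    def test_inverse_n_scaling(self):
        v1 = an.permutation_marginal(2.0, 3.0, 1000, 1.5, "asymptotic")
        v2 = an.permutation_marginal(2.0, 3.0, 2000, 1.5, "asymptotic")
        assert np.isclose(v2, v1 / 2)

    def test_cutoff_violation_warns(self):
        with pytest.warns(RuntimeWarning):
            an.permutation_marginal(100.0, 100.0, 100, 1.0, "asymptotic")

    def test_modes_converge_when_sparse(self):
        integral = an.permutation_marginal(1.0, 2.0, 10**5, 2.0, "integral")
        asym = an.permutation_marginal(1.0, 2.0, 10**5, 2.0, "asymptotic")
        assert abs(integral / asym - 1.0) < 0.01
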