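import numpy as np
import pytest
from scipy.special import expit

from xtalknet.p1_bayes import (
    P1Config,
    _sample_pg,
    brute_force_posterior,
    dyad_probabilities,
    edge_probability,
    gibbs_fit,
    log_likelihood,
    posterior_edge_probs,
)

from conftest import make_network

SAMPLERS = ["polya_gamma", "metropolis_within_gibbs"]


class TestDyadProbability:
    def test_logistic_at_zero(self):
        assert edge_probability(0.0, 0.0, 0.0) == pytest.approx(0.5)

    def test_extreme_density_limit_and_complement(self):
        p1, p0 = dyad_probabilities(-800.0, 0.0, 0.0)
        assert p1 == 0.0 and p0 == 1.0
        p1, p0 = dyad_probabilities(0.7, -1.2, 2.0)
        assert p1 + p0 == 1.0  # exact, by the normalization constraint

    def test_closed_form(self):
        expected = np.exp(0.9) / (1 + np.exp(0.9))
        assert edge_probability(1.0, -0.3, 0.2) == pytest.approx(expected, rel=1e-12)


class TestLogLikelihood:
    def test_empty_and_complete_three_node_symmetry(self):
        empty = make_network(3, [])
        full = make_network(3, [(0, 1), (0, 2), (1, 2)])
        assert log_likelihood(empty, 0.0, np.zeros(3)) == pytest.approx(3 * np.log(0.5))
        assert log_likelihood(full, 0.0, np.zeros(3)) == pytest.approx(3 * np.log(0.5))

    def test_matches_term_by_term_enumeration(self, rng):
        g = 6
        edges = [(i, j) for i in range(g) for j in range(i + 1, g) if rng.random() < 0.5]
        net = make_network(g, edges)
        theta, alpha = 0.4, rng.standard_normal(g)
        expected = 0.0
        for i in range(g):
            for j in range(i + 1, g):
                p = expit(theta + alpha[i] + alpha[j])
                expected += np.log(p) if net.adjacency[i, j] else np.log(1 - p)
        assert log_likelihood(net, theta, alpha) == pytest.approx(expected, rel=1e-10)


class TestPolyaGamma:
    def test_mean_matches_closed_form(self, rng):
        # E[PG(1, z)] = tanh(z/2) / (2 z), with limit 1/4 at z = 0
        for z, exact in [(0.0, 0.25), (2.0, np.tanh(1.0) / 4.0),
                         (6.0, np.tanh(3.0) / 12.0)]:
            draws = _sample_pg(np.full(30_000, z), rng)
            assert draws.mean() == pytest.approx(exact, abs=0.002)
            assert (draws > 0).all()


@pytest.fixture(scope="module")
def small_posterior():
    net_r = make_network(4, [(0, 1), (1, 2)])
    net_p = make_network(4, [(2, 3)])
    config = P1Config(seed=3, n_iter=700, burn_in=500)
    return gibbs_fit(net_r, net_p, config)


class TestGibbsFit:
    def test_draw_shapes_and_hyperparameter_positivity(self, small_posterior):
        post = small_posterior
        assert post.theta.shape == (200, 2)
        assert post.alpha.shape == (200, 4, 2)
        assert (post.tau_theta > 0).all()
        for s in post.sigma:
            assert np.allclose(s, s.T)
            assert np.linalg.eigvalsh(s).min() > 0

    def test_edge_probs_symmetric_unit_interval(self, small_posterior):
        for m in (small_posterior.edge_prob_R, small_posterior.edge_prob_P):
            np.testing.assert_allclose(m, m.T)
            assert (m >= 0).all() and (m <= 1).all()
            assert np.diag(m).max() == 0

    def test_reproducible_given_seed(self):
        net_r = make_network(5, [(0, 1), (2, 3)])
        net_p = make_network(5, [(1, 4)])
        cfg = dict(seed=11, n_iter=400, burn_in=300)
        a = gibbs_fit(net_r, net_p, P1Config(**cfg))
        b = gibbs_fit(net_r, net_p, P1Config(**cfg))
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.edge_prob_R, b.edge_prob_R)

    def test_mismatched_gene_lists_rejected(self):
        a = make_network(3, [], gene_ids=list("ABC"))
        b = make_network(3, [], gene_ids=list("ABD"))
        with pytest.raises(ValueError, match="gene_ids"):
            gibbs_fit(a, b, P1Config(seed=0, n_iter=200, burn_in=100))

    def test_density_ordering_of_theta(self):
        # empty resistant vs complete parental network: theta_R < theta_P
        g = 8
        net_r = make_network(g, [])
        net_p = make_network(g, [(i, j) for i in range(g) for j in range(i + 1, g)])
        post = gibbs_fit(net_r, net_p, P1Config(seed=2, n_iter=800, burn_in=500))
        assert post.theta[:, 0].mean() < post.theta[:, 1].mean()

    def test_identical_networks_give_positive_propensity_correlation(self):
        g = 6
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 4), (2, 5), (3, 4), (4, 5)]
        net = make_network(g, edges)
        post = gibbs_fit(net, net, P1Config(seed=4, n_iter=1500, burn_in=500))
        corr = post.sigma[:, 0, 1] / np.sqrt(post.sigma[:, 0, 0] * post.sigma[:, 1, 1])
        assert corr.mean() > 0

    def test_permutation_equivariance_of_edge_probs(self):
        g = 5
        edges = [(0, 1), (0, 2), (3, 4)]
        perm = [2, 0, 4, 1, 3]
        net_r = make_network(g, edges)
        net_p = make_network(g, [(1, 3)])
        inv = np.argsort(perm)
        pedges_r = [(min(inv[i], inv[j]), max(inv[i], inv[j])) for i, j in edges]
        pnet_r = make_network(g, pedges_r)
        pnet_p = make_network(g, [(min(inv[1], inv[3]), max(inv[1], inv[3]))])
        cfg = dict(n_iter=4000, burn_in=1000)
        post = gibbs_fit(net_r, net_p, P1Config(seed=9, **cfg))
        ppost = gibbs_fit(pnet_r, pnet_p, P1Config(seed=10, **cfg))
        back = ppost.edge_prob_R[np.ix_(inv, inv)]
        np.testing.assert_allclose(back, post.edge_prob_R, atol=0.06)


class TestPosteriorEdgeProbs:
    def test_mean_estimator_single_regime(self, small_posterior):
        ep_r, ep_p = posterior_edge_probs(small_posterior, "mean")
        np.testing.assert_allclose(ep_r, small_posterior.edge_prob_R, atol=1e-12)
        np.testing.assert_allclose(ep_p, small_posterior.edge_prob_P, atol=1e-12)

    def test_draws_estimator_binomial_concentration(self, small_posterior):
        # clamp the chain at theta = alpha = 0: every dyad is a fair coin
        post = small_posterior
        frozen = type(post)(
            gene_ids=post.gene_ids,
            theta=np.zeros((1000, 2)),
            alpha=np.zeros((1000, 4, 2)),
            sigma=np.tile(np.eye(2), (1000, 1, 1)),
            tau_theta=np.ones((1000, 2)),
            edge_prob_R=post.edge_prob_R,
            edge_prob_P=post.edge_prob_P,
            config=post.config,
        )
        ep_r, _ = posterior_edge_probs(frozen, "draws", seed=1)
        iu = np.triu_indices(4, 1)
        assert np.abs(ep_r[iu] - 0.5).max() < 0.05

    def test_estimators_agree_within_binomial_error(self, small_posterior):
        mean_r, mean_p = posterior_edge_probs(small_posterior, "mean")
        draw_r, draw_p = posterior_edge_probs(small_posterior, "draws", seed=2)
        n = small_posterior.n_draws
        for m, d in ((mean_r, draw_r), (mean_p, draw_p)):
            se = np.sqrt(np.maximum(m * (1 - m), 1e-4) / n)
            iu = np.triu_indices(4, 1)
            assert (np.abs(d[iu] - m[iu]) <= 3 * se[iu] + 1e-9).all()


class TestBruteForceOracle:
    GRID_T = np.linspace(-6, 6, 49)
    GRID_A = np.linspace(-4, 4, 33)

    def test_automorphic_nodes_have_equal_edge_probabilities(self):
        # nodes 0 and 1 are exchangeable in a path 0-2-1
        net = make_network(3, [(0, 2), (1, 2)])
        ep, _ = brute_force_posterior(
            net, make_network(3, []), self.GRID_T, self.GRID_A, np.eye(2), 0.25
        )
        assert ep[0, 2] == pytest.approx(ep[1, 2], abs=1e-6)

    def test_grid_refinement_stable(self):
        net_r = make_network(2, [(0, 1)])
        net_p = make_network(2, [])
        coarse = brute_force_posterior(
            net_r, net_p, np.linspace(-6, 6, 25), np.linspace(-4, 4, 17),
            np.eye(2), 0.25,
        )
        fine = brute_force_posterior(
            net_r, net_p, np.linspace(-6, 6, 49), np.linspace(-4, 4, 33),
            np.eye(2), 0.25,
        )
        assert abs(coarse[0][0, 1] - fine[0][0, 1]) < 0.01
        assert abs(coarse[1][0, 1] - fine[1][0, 1]) < 0.01

    def test_one_dyad_quadrature_with_clamped_alpha(self):
        # alpha clamped to zero: the posterior is 1-D quadrature over theta
        net_r = make_network(2, [(0, 1)])
        net_p = make_network(2, [])
        ep_r, ep_p = brute_force_posterior(
            net_r, net_p, np.linspace(-8, 8, 2001), np.array([0.0]), np.eye(2), 0.25
        )
        theta = np.linspace(-8, 8, 2001)
        w = np.exp(-0.5 * theta ** 2 * 0.25)
        p = expit(theta)
        assert ep_r[0, 1] == pytest.approx((w * p * p).sum() / (w * p).sum(), abs=1e-9)
        assert ep_p[0, 1] == pytest.approx(
            (w * (1 - p) * p).sum() / (w * (1 - p)).sum(), abs=1e-9
        )

    @pytest.mark.parametrize("sampler", SAMPLERS)
    def test_gibbs_matches_oracle_on_a_dyad(self, sampler):
        net_r = make_network(2, [(0, 1)])
        net_p = make_network(2, [])
        bf_r, bf_p = brute_force_posterior(
            net_r, net_p, self.GRID_T, self.GRID_A, np.eye(2), 0.25
        )
        post = gibbs_fit(
            net_r, net_p,
            P1Config(seed=7, n_iter=1500, burn_in=500, sampler=sampler,
                     fixed_sigma=np.eye(2), fixed_tau_theta=0.25),
        )
        assert post.edge_prob_R[0, 1] == pytest.approx(bf_r[0, 1], abs=0.05)
        assert post.edge_prob_P[0, 1] == pytest.approx(bf_p[0, 1], abs=0.05)

    def test_nondiagonal_sigma_rejected(self):
        net = make_network(2, [])
        with pytest.raises(NotImplementedError):
            brute_force_posterior(
                net, net, self.GRID_T, self.GRID_A,
                np.array([[1.0, 0.5], [0.5, 1.0]]), 1.0,
            )


class TestConfigValidation:
    def test_burn_in_bounds(self):
        with pytest.raises(ValueError):
            P1Config(seed=0, n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            P1Config(seed=0, n_iter=150, burn_in=100)  # < 100 retained

    def test_unknown_sampler_and_estimator(self):
        with pytest.raises(ValueError):
            P1Config(seed=0, sampler="winbugs")
        with pytest.raises(ValueError):
            P1Config(seed=0, edge_prob_estimator="mode")

    def test_wishart_scale_must_be_spd(self):
        with pytest.raises(ValueError):
            P1Config(seed=0, wishart_scale=np.zeros((2, 2)))
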