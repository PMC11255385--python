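"""Mixture initialization, graph coercion, M-steps and Baum-Welch."""

import warnings

import numpy as np
import pytest
import scipy.optimize

from locusmix.data import AlleleCountDataset
from locusmix.emissions import cluster_sample_sizes
from locusmix.fitting import (
    FitConfig,
    _EmissionQ,
    baum_welch,
    coerce_to_graph,
    gmm_em,
    init_covariance,
    m_step_branch_lengths,
    m_step_root,
    m_step_transition,
    moment_sigma2,
    select_num_components,
    fit,
)
from locusmix.graph import drift_covariance, parse_graph
from locusmix.hmm import (
    EdgeTransition,
    HiddenStateSpace,
    MigrationGrid,
    rate_matrix,
    uniform_grid,
)
from locusmix.simulate import simulate_dataset, simulate_track


def _small_dataset(graph, rate, L=200, seed=0, sigma2=0.3, N=100):
    track = simulate_track(L, "constant", rate=rate) if graph.I else []
    ds, _ = simulate_dataset(graph, graph.branch_lengths(), track, mu=-0.5,
                             sigma2=sigma2, N=N, seed=seed,
                             n_loci=None if graph.I else L)
    return ds.drop_monomorphic()


class TestInitCovariance:
    def test_duplicated_population_gives_perfect_correlation(self, rng):
        x = rng.normal(size=(100, 1))
        d = np.hstack([x, x])
        with pytest.warns(UserWarning, match="rank-deficient"):
            W0 = init_covariance(d)  # singular: ridge added with a warning
        assert W0[0, 1] == pytest.approx(W0[0, 0], abs=1e-5)

    def test_monte_carlo_recovery(self, two_pop_mig):
        ds = _small_dataset(two_pop_mig, 0.3, L=100_000, sigma2=0.0, N=10_000)
        S_true = drift_covariance(two_pop_mig, two_pop_mig.branch_lengths(),
                                  [0.3]) + np.eye(2) / 10_000
        W0 = init_covariance(ds.d)
        assert np.linalg.norm(W0 - S_true) / np.linalg.norm(S_true) < 0.05

    def test_constant_input_gets_ridge(self):
        d = np.ones((10, 2))
        with pytest.warns(UserWarning, match="rank-deficient"):
            W0 = init_covariance(d)
        assert np.linalg.eigvalsh(W0).min() > 0


class TestGmmEm:
    def test_single_component_matches_direct_mle(self, rng):
        # oracle: numerical MLE of N(mu*1, C) with free SPD C, shared mean
        d = rng.multivariate_normal([-0.4, -0.4], [[0.3, 0.25], [0.25, 0.35]],
                                    size=400)
        sigma_bar = np.zeros((2, 2))
        mix = gmm_em(d, sigma_bar, 1, seed=0, sigma2=0.1)

        def nll(x):
            mu = x[0]
            Lm = np.array([[np.exp(x[1]), 0], [x[2], np.exp(x[3])]])
            C = Lm @ Lm.T
            r = d - mu
            Cinv = np.linalg.inv(C)
            return 0.5 * (len(d) * (2 * np.log(2 * np.pi)
                                    + np.log(np.linalg.det(C)))
                          + np.einsum("lm,mn,ln->", r, Cinv, r))

        res = scipy.optimize.minimize(nll, [0.0, -1.0, 0.1, -1.0],
                                      method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-10,
                                               "maxiter": 5000})
        assert mix.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_responsibilities_normalized(self, rng):
        d = rng.normal(size=(300, 3))
        mix = gmm_em(d, np.zeros((3, 3)), 2, seed=1, sigma2=0.05)
        assert np.allclose(mix.responsibilities.sum(axis=1), 1.0, atol=1e-12)
        assert mix.pi.sum() == pytest.approx(1.0)

    def test_two_regime_weight_recovery(self, rng):
        # well-separated covariance regimes at 50/50 proportions
        C1 = np.array([[0.05, 0.0], [0.0, 0.05]])
        C2 = np.array([[0.6, 0.55], [0.55, 0.6]])
        d = np.vstack([
            rng.multivariate_normal([-0.5, -0.5], C1, size=5000),
            rng.multivariate_normal([-0.5, -0.5], C2, size=5000),
        ])
        mix = gmm_em(d, np.zeros((2, 2)), 2, seed=2, sigma2=0.01)
        assert np.allclose(np.sort(mix.pi), [0.5, 0.5], atol=0.05)
        # independent cross-check: sklearn's unconstrained mixture agrees
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(2, covariance_type="full", random_state=0).fit(d)
        assert np.allclose(np.sort(gm.weights_), np.sort(mix.pi), atol=0.05)

    def test_loglik_monotone(self, rng):
        d = rng.normal(size=(500, 2)) * [0.5, 0.8]
        trace = []
        orig = gmm_em.__wrapped__ if hasattr(gmm_em, "__wrapped__") else None
        # run EM manually through the public function twice with tighter tol;
        # monotonicity is asserted inside via the returned loglik ordering
        m1 = gmm_em(d, np.zeros((2, 2)), 2, seed=3, sigma2=0.05, max_iter=3)
        m2 = gmm_em(d, np.zeros((2, 2)), 2, seed=3, sigma2=0.05, max_iter=30)
        assert m2.loglik >= m1.loglik - 1e-8


class TestCoercion:
    def test_noiseless_recovery(self, four_pop_tip):
        g = four_pop_tip
        c_true = g.branch_lengths()
        W_target = drift_covariance(g, c_true, [0.35])
        c, w, rss = coerce_to_graph([W_target], np.array([1.0]), g,
                                    restarts=40, seed=0)
        assert rss < 1e-8
        assert np.abs(w[0, 0] - 0.35) < 1e-3
        assert np.abs(c - c_true).max() < 1e-3

    def test_tree_reduces_to_least_squares(self, two_pop_tree):
        # I=0, R=1: exact weighted least squares; residual orthogonal to
        # the column space of the design
        W_target = np.array([[0.04, 0.01], [0.01, 0.025]])
        c, w, rss = coerce_to_graph([W_target], np.array([1.0]), two_pop_tree,
                                    restarts=1, seed=0)
        W_fit = drift_covariance(two_pop_tree, c, np.zeros(0))
        resid = (W_target - W_fit).ravel()
        from locusmix.graph import branch_inclusion_probabilities

        P = branch_inclusion_probabilities(two_pop_tree, np.zeros(0))
        for k in range(two_pop_tree.K):
            col = np.outer(P[:, k], P[:, k]).ravel()
            assert abs(resid @ col) < 1e-6

    def test_component_permutation_symmetry(self, four_pop_tip):
        g = four_pop_tip
        c_true = g.branch_lengths()
        W1 = drift_covariance(g, c_true, [0.1])
        W2 = drift_covariance(g, c_true, [0.6])
        ca, wa, _ = coerce_to_graph([W1, W2], np.array([0.5, 0.5]), g,
                                    restarts=30, seed=5)
        cb, wb, _ = coerce_to_graph([W2, W1], np.array([0.5, 0.5]), g,
                                    restarts=30, seed=5)
        assert np.allclose(np.sort(wa.ravel()), np.sort(wb.ravel()), atol=1e-3)
        assert np.allclose(ca, cb, atol=1e-3)


class TestSelectComponents:
    def test_threshold_one_forces_single_component(self, two_pop_mig, rng):
        ds = _small_dataset(two_pop_mig, 0.3, L=300, seed=4)
        cfg = FitConfig(restarts=10, pi_threshold=1.0, seed=0)
        clusters = cluster_sample_sizes(ds.N, 3)
        mix, c, rates = select_num_components(ds.d, clusters.mean_sigma(),
                                              two_pop_mig, cfg)
        assert mix.R == 1

    def test_single_regime_data_selects_one(self, two_pop_mig):
        ds = _small_dataset(two_pop_mig, 0.3, L=2000, seed=5)
        cfg = FitConfig(restarts=10, max_components=3, seed=1)
        clusters = cluster_sample_sizes(ds.N, 3)
        mix, _, _ = select_num_components(ds.d, clusters.mean_sigma(),
                                          two_pop_mig, cfg)
        assert mix.R == 1


class TestMStepRoot:
    def _single_state_eq(self, graph, ds, clusters):
        gamma = np.ones((ds.L, 1))
        return _EmissionQ(graph, np.zeros((1, graph.I)), clusters, gamma, ds.d)

    def test_identity_covariance_gives_grand_mean(self, two_pop_tree, rng):
        # plug S = I into the GLS formula: mu is the grand mean of d
        d = rng.normal(size=(50, 2))
        n = ((np.sin(np.clip(d, -1.5, 1.5)) + 1) / 2 * 100).astype(int)
        ds = AlleleCountDataset(n, np.full((50, 2), 100), np.array(["1"] * 50),
                               1000.0 * np.arange(1, 51), ["pop1", "pop2"])
        clusters = cluster_sample_sizes(ds.N, 1)
        eq = self._single_state_eq(two_pop_tree, ds, clusters)
        # identity S: c=(0.495, 0.495) making diag 0.5+0.495+0.005=1... use direct check instead
        c = np.array([0.0, 0.0])
        mu = eq.optimal_mu(c, 1e-9)
        # with S ~ diag(1/100) equal across populations the GLS mean is the
        # plain grand mean
        assert mu == pytest.approx(ds.d.mean(), abs=1e-6)

    def test_q_maximized_at_mu_star(self, two_pop_mig):
        ds = _small_dataset(two_pop_mig, 0.2, L=400, seed=6)
        clusters = cluster_sample_sizes(ds.N, 2)
        gamma = np.ones((ds.L, 1))
        eq = _EmissionQ(two_pop_mig, np.array([[0.2]]), clusters, gamma, ds.d)
        c = two_pop_mig.branch_lengths()
        mu, s2 = m_step_root(eq, c, -0.3, 0.2)
        q_star = eq.q(c, mu, s2)
        for eps in (1e-3, -1e-3):
            assert q_star >= eq.q(c, mu + eps, s2) - 1e-9
            assert q_star >= eq.q(c, mu, s2 * (1 + eps)) - 1e-9

    def test_sigma2_recovery(self, four_pop_tip):
        # known c and w, sigma^2 = 0.3 truth; single-state Q update
        ds = _small_dataset(four_pop_tip, 0.3, L=10_000, seed=7)
        clusters = cluster_sample_sizes(ds.N, 1)
        gamma = np.ones((ds.L, 1))
        eq = _EmissionQ(four_pop_tip, np.array([[0.3]]), clusters, gamma, ds.d)
        mu, s2 = m_step_root(eq, four_pop_tip.branch_lengths(), -0.5, 0.1)
        assert abs(s2 - 0.3) < 0.05
        assert abs(mu - (-0.5)) < 0.05


class TestMStepBranchLengths:
    def test_gradient_matches_finite_differences(self, two_pop_mig):
        ds = _small_dataset(two_pop_mig, 0.4, L=300, seed=8)
        clusters = cluster_sample_sizes(ds.N, 2)
        rng = np.random.default_rng(0)
        gamma = rng.dirichlet(np.ones(3), size=ds.L)
        rates = np.array([[0.0], [0.5], [1.0]])
        eq = _EmissionQ(two_pop_mig, rates, clusters, gamma, ds.d)
        c = two_pop_mig.branch_lengths()
        g_an = eq.grad_c(c, -0.5, 0.3)
        h = 1e-7
        for k in range(len(c)):
            ck = c.copy()
            ck[k] += h
            g_fd = (eq.q(ck, -0.5, 0.3) - eq.q(c, -0.5, 0.3)) / h
            assert g_an[k] == pytest.approx(g_fd, rel=1e-4, abs=1e-6)

    def test_q_non_decreasing(self, two_pop_mig):
        ds = _small_dataset(two_pop_mig, 0.4, L=300, seed=9)
        clusters = cluster_sample_sizes(ds.N, 2)
        gamma = np.ones((ds.L, 1))
        eq = _EmissionQ(two_pop_mig, np.array([[0.4]]), clusters, gamma, ds.d)
        c0 = two_pop_mig.branch_lengths() * 2.0
        q0 = eq.q(c0, -0.5, 0.3)
        c1 = m_step_branch_lengths(eq, c0, -0.5, 0.3)
        assert eq.q(c1, -0.5, 0.3) >= q0

    def test_one_branch_closed_form_fixed_point(self):
        # M=1: S = 1/N + c + sigma^2, MLE of c matches moment matching
        g = parse_graph("ROOT R\nBRANCH R P1 0.05\nLEAF P1 a")
        rng = np.random.default_rng(1)
        L, N, sigma2, mu = 4000, 100, 0.0, -0.2
        c_true = 0.08
        d = (mu + rng.normal(size=L) * np.sqrt(c_true + 1 / N)).reshape(-1, 1)
        n = np.clip(((np.sin(np.clip(d, -1.5, 1.5)) + 1) / 2 * N), 0, N)
        ds = AlleleCountDataset(n.astype(int), np.full((L, 1), N),
                               np.array(["1"] * L), 1000.0 * np.arange(1, L + 1),
                               ["a"])
        clusters = cluster_sample_sizes(ds.N, 1)
        gamma = np.ones((L, 1))
        eq = _EmissionQ(g, np.zeros((1, 0)), clusters, gamma, ds.d)
        closed = float(np.mean((ds.d - mu) ** 2) - 1 / N)  # scalar calculus
        c_hat = m_step_branch_lengths(eq, np.array([0.02]), mu, 1e-12,
                                      max_newton=40)
        assert c_hat[0] == pytest.approx(closed, rel=1e-4)


class TestMStepTransition:
    def test_kappa_recovery_from_chain_counts(self):
        # hard transition counts from a long simulated chain, no emissions
        J, kappa_true, delta = 5, 1.3, 0.7
        grid = MigrationGrid([uniform_grid(J)])
        edge = EdgeTransition(rate_matrix(J, "ladder"), kappa_true)
        rng = np.random.default_rng(0)
        P = edge.P(delta)
        L = 40_000
        states = np.empty(L, int)
        states[0] = rng.integers(J)
        for l in range(1, L):
            states[l] = rng.choice(J, p=P[states[l - 1]])
        xi = np.zeros((J, J))
        np.add.at(xi, (states[:-1], states[1:]), 1.0)
        first = np.zeros(J)
        first[states[0]] = 1.0
        kappa, _, _ = m_step_transition([{delta: xi}], [first], grid, "ladder",
                                        np.array([0.4]))
        assert abs(kappa[0] - kappa_true) / kappa_true < 0.10

    def test_q_beats_random_probes_and_constraints(self, rng):
        J = 4
        grid = MigrationGrid([uniform_grid(J)])
        xi = rng.uniform(0.1, 5.0, size=(J, J))
        first = rng.dirichlet(np.ones(J))
        kappa, phi, zeta = m_step_transition(
            [{1.0: xi}], [first], grid, "attractor", np.array([1.0]),
            np.array([0.5]), np.array([0.5]), np.array([1]))
        assert 0 < phi[0] <= 1 and 0 < zeta[0] <= 1

        def q(kap, ph, ze):
            from locusmix.hmm import TransitionModel

            sub = TransitionModel("attractor", grid, [kap], np.array([ph]),
                                  np.array([ze]), np.array([1]))
            P = sub.edges[0].P(1.0)
            return float(np.sum(xi * np.log(P))
                         + first @ np.log(sub.edges[0].pi))

        q_star = q(kappa[0], phi[0], zeta[0])
        for _ in range(10):
            probe = q(float(rng.uniform(0.1, 5)), float(rng.uniform(0.05, 1)),
                      float(rng.uniform(0.05, 1)))
            assert q_star >= probe - 1e-9


class TestBaumWelch:
    def test_monotone_trace(self, two_pop_mig):
        ds = _small_dataset(two_pop_mig, 0.3, L=150, seed=10)
        space = HiddenStateSpace(MigrationGrid([uniform_grid(3)]))
        cfg = FitConfig(max_iter=25, sigma_clusters=2, seed=0, squarem=False)
        m = baum_welch(ds, two_pop_mig, space, "ladder",
                       c0=two_pop_mig.branch_lengths(), mu0=-0.4, sigma20=0.2,
                       kappa0=np.array([1.0]), config=cfg)
        finite = [x for x in m.trace if np.isfinite(x)]
        assert np.all(np.diff(finite) > -1e-8 * (np.abs(finite[:-1]) + 1))

    def test_single_state_matches_direct_mle(self, two_pop_tree):
        # J=1 grid: no HMM left; final likelihood equals the numerical MLE
        # of the plain Gaussian model
        ds = _small_dataset(two_pop_tree, 0.0, L=120, seed=11)
        space = HiddenStateSpace(MigrationGrid([]))
        cfg = FitConfig(max_iter=400, tol=1e-12, sigma_clusters=1, seed=0)
        m = baum_welch(ds, two_pop_tree, space, "ladder",
                       c0=np.array([0.02, 0.02]), mu0=-0.3, sigma20=0.2,
                       kappa0=np.zeros(0), config=cfg)
        clusters = cluster_sample_sizes(ds.N, 1)
        sig = clusters.sigma(0)

        def nll(x):
            c = x[:2]
            mu, s2 = x[2], np.exp(x[3])
            S = np.diag(c) + sig + s2
            try:
                cf = scipy.linalg.cho_factor(S)
            except np.linalg.LinAlgError:
                return 1e12
            logdet = 2 * np.sum(np.log(np.diag(cf[0])))
            r = ds.d - mu
            quad = np.einsum("lm,lm->l", r, scipy.linalg.cho_solve(cf, r.T).T)
            return 0.5 * (ds.L * (2 * np.log(2 * np.pi) + logdet) + quad.sum())

        import scipy.linalg

        res = scipy.optimize.minimize(
            nll, [0.02, 0.02, -0.3, np.log(0.2)], method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 20000,
                     "maxfev": 20000})
        assert m.loglik == pytest.approx(-res.fun, abs=1e-6)

    def test_squarem_parity_and_speed(self, two_pop_mig):
        ds = _small_dataset(two_pop_mig, 0.3, L=120, seed=12)
        space = HiddenStateSpace(MigrationGrid([uniform_grid(3)]))
        wins = 0
        for seed in range(3):
            kw = dict(c0=two_pop_mig.branch_lengths(), mu0=-0.4, sigma20=0.2,
                      kappa0=np.array([1.0]))
            m_on = baum_welch(ds, two_pop_mig, space, "ladder",
                              config=FitConfig(max_iter=120, tol=1e-8,
                                               sigma_clusters=2, seed=seed),
                              **kw)
            m_off = baum_welch(ds, two_pop_mig, space, "ladder",
                               config=FitConfig(max_iter=120, tol=1e-8,
                                                sigma_clusters=2, seed=seed,
                                                squarem=False), **kw)
            assert m_on.loglik == pytest.approx(m_off.loglik, abs=1e-4)
            if m_on.n_iter <= m_off.n_iter:
                wins += 1
        assert wins >= 2


class TestAttractorSearch:
    def test_selection_rule_and_candidates(self, two_pop_mig):
        from locusmix.fitting import attractor_search

        track = simulate_track(250, "markov", grid=uniform_grid(5), kappa=0.05,
                               variant="attractor", phi=0.2, zeta=0.6,
                               attractor=1, seed=17)
        ds, _ = simulate_dataset(two_pop_mig, two_pop_mig.branch_lengths(),
                                 track, mu=-0.5, sigma2=0.3, N=100, seed=17)
        ds = ds.drop_monomorphic()
        space = HiddenStateSpace(MigrationGrid([uniform_grid(5)]))
        cfg = FitConfig(max_iter=60, tol=1e-6, sigma_clusters=2, top_states=3,
                        seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ladder = baum_welch(ds, two_pop_mig, space, "ladder",
                                c0=two_pop_mig.branch_lengths(), mu0=-0.5,
                                sigma20=0.3, kappa0=np.array([0.05]),
                                config=cfg)
            best = attractor_search(ds, two_pop_mig, space, ladder, cfg)
        # the selected model never loses to the ladder fit it started from
        assert best.loglik >= ladder.loglik - 1e-6
        if best.variant == "attractor":
            assert 0 < best.phi[0] <= 1 and 0 < best.zeta[0] <= 1


class TestFitPipeline:
    def test_toy_end_to_end_and_determinism(self, two_pop_mig):
        ds = _small_dataset(two_pop_mig, 0.3, L=200, seed=13)
        cfg = FitConfig(restarts=8, grid_size=3, sigma_clusters=2, max_iter=10,
                        max_components=1, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1, s1 = fit(ds, two_pop_mig, cfg, ladder_only=True)
            m2, s2 = fit(ds, two_pop_mig, cfg, ladder_only=True)
        assert np.allclose(s1.state_posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(s1.state_posteriors, s2.state_posteriors)
        assert np.array_equal(m1.c, m2.c)
        assert np.all(s1.mean_rate >= 0) and np.all(s1.mean_rate <= 1)
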