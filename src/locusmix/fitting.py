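"""Empirical-Bayes fitting: mixture initialization, graph coercion and
SQUAREM-accelerated Baum-Welch.

The recipe:

1. sample covariance of the transformed frequencies as a first guess;
2. a Gaussian mixture (shared root prior, free component covariances)
   refines it into R regime-specific covariances W_r;
3. the W_r are coerced onto the graph, yielding shared branch lengths c
   and per-regime migration rates (weighted residual sum of squares,
   Nelder-Mead over rates with c profiled out by linear least squares);
4. R grows while every mixture weight exceeds a threshold and the
   weighted RSS keeps dropping;
5. Baum-Welch with the attractor-free ladder transition model;
6. the top-T states by mean posterior are tried as attractors, each with
   its own Baum-Welch run, and the highest-likelihood model wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
from scipy.linalg import cho_factor, cho_solve

from .data import AlleleCountDataset
from .emissions import EmissionTable, SampleSizeClusters, cluster_sample_sizes
from .graph import PopulationGraph, branch_inclusion_probabilities
from .hmm import (
    ForwardBackwardResult,
    HiddenStateSpace,
    MigrationGrid,
    PosteriorSummary,
    TransitionModel,
    forward_backward,
    posterior_summaries,
    uniform_grid,
)

__all__ = [
    "FitConfig",
    "MixtureInit",
    "FittedModel",
    "init_covariance",
    "gmm_em",
    "coerce_to_graph",
    "select_num_components",
    "baum_welch",
    "attractor_search",
    "fit",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FitConfig:
    """Tunable knobs of the fitting recipe (defaults follow the method)."""

    restarts: int = 1000          # C: coercion Nelder-Mead restarts
    top_states: int = 5           # T: attractor candidates
    pi_threshold: float = 0.2     # minimum mixture weight to accept a component
    grid_size: int = 21           # J: per-edge migration-rate grid
    sigma_clusters: int = 10      # u: sample-size covariance clusters
    tol: float = 1e-6             # relative log-likelihood convergence
    max_iter: int = 500           # Baum-Welch iterations
    gmm_tol: float = 1e-8
    gmm_max_iter: int = 500
    max_components: int = 6
    squarem: bool = True
    keep_monomorphic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.pi_threshold <= 1.0):
            raise ValueError("pi threshold must lie in (0, 1]")
        for name in ("restarts", "top_states", "grid_size", "sigma_clusters",
                     "max_iter", "max_components"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class MixtureInit:
    """Result of the Gaussian-mixture refinement (step 2)."""

    R: int
    pi: np.ndarray                # (R,)
    W: list[np.ndarray]           # per-component drift covariances (PSD-projected)
    mu: float
    sigma2: float
    assignment: np.ndarray        # (L,) hard component labels
    responsibilities: np.ndarray  # (L, R)
    loglik: float
    rss: float = np.nan           # weighted RSS of the graph coercion, if done


@dataclass
class FittedModel:
    """Learned parameters of the genome-scan model."""

    graph: PopulationGraph        # with fitted branch lengths
    c: np.ndarray
    mu: float
    sigma2: float
    variant: str                  # "ladder" or "attractor"
    kappa: np.ndarray
    phi: np.ndarray | None
    zeta: np.ndarray | None
    attractor: np.ndarray | None  # (I,) 0-based grid indices
    grid: MigrationGrid
    loglik: float
    n_iter: int
    converged: bool
    negative_branch_lengths: bool
    distance_rescale: float = 1.0
    trace: list[float] = field(default_factory=list)

    def transition_model(self) -> TransitionModel:
        return TransitionModel(self.variant, self.grid, self.kappa,
                               self.phi, self.zeta, self.attractor)


# ---------------------------------------------------------------------------
# step 1-2: covariance initialization and mixture refinement

def init_covariance(d: np.ndarray) -> np.ndarray:
    """Sample covariance of the transformed frequencies across loci.

    Adds a small ridge (with a warning) if the estimate is rank
    deficient, e.g. when L is barely above M.
    """
    d = np.asarray(d, float)
    L, M = d.shape
    if L < M + 1:
        raise ValueError("need at least M+1 loci for a covariance estimate")
    W0 = np.cov(d.T, bias=False).reshape(M, M)
    if np.linalg.matrix_rank(W0, tol=1e-10) < M:
        warnings.warn("rank-deficient initial covariance; adding ridge")
        W0 = W0 + 1e-6 * np.eye(M)
    return W0


def _psd_project(A: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (A + A.T))
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def moment_sigma2(d: np.ndarray, floor: float = 1e-3) -> float:
    """Moment estimate of the root-prior variance sigma^2.

    Every pairwise covariance of d equals sigma^2 plus a non-negative
    shared-drift term, and population pairs on opposite sides of the
    root share (almost) no drift, so the *minimum* off-diagonal sample
    covariance estimates sigma^2 with the least drift contamination.
    """
    M = d.shape[1]
    C = np.cov(np.asarray(d, float).T, bias=False).reshape(M, M)
    if M == 1:
        return max(floor, float(C[0, 0]) * 0.5)
    off = C[~np.eye(M, dtype=bool)]
    return max(floor, float(off.min()))


def gmm_em(d: np.ndarray, sigma_bar: np.ndarray, R: int, seed: int = 0, *,
           sigma2: float | None = None, tol: float = 1e-8, max_iter: int = 500,
           max_retries: int = 5) -> MixtureInit:
    """Gaussian mixture with shared root prior: d_l ~ sum_r pi_r N(mu*1, C_r).

    The component covariances C_r are free SPD matrices during EM (ECM
    updates: mu by generalized least squares, C_r by responsibility-
    weighted scatter), which keeps the likelihood exactly monotone.  On
    return each C_r is decomposed as W_r + sigma_bar + sigma^2*11' with
    W_r projected to the nearest PSD matrix; sigma^2 is not separately
    identifiable here and is held at a moment estimate unless supplied.
    """
    d = np.asarray(d, float)
    L, M = d.shape
    if R < 1:
        raise ValueError("R must be >= 1")
    if sigma2 is None:
        sigma2 = moment_sigma2(d)
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + 1000 * attempt)
        out = _gmm_em_once(d, R, rng, tol, max_iter)
        if out is not None:
            pi, C, mu, resp, ll = out
            ones = np.ones((M, M))
            W = [_psd_project(Cr - sigma_bar - sigma2 * ones) for Cr in C]
            return MixtureInit(R, pi, W, mu, float(sigma2),
                               np.argmax(resp, axis=1), resp, ll)
    raise RuntimeError("mixture EM collapsed repeatedly; reduce R")


def _gmm_em_once(d, R, rng, tol, max_iter):
    L, M = d.shape
    mu = float(d.mean())
    # seed components from perturbed per-subset scatters
    resp = rng.dirichlet(np.full(R, 5.0), size=L)
    C = []
    r0 = d - mu
    base = (r0.T @ r0) / L
    for r in range(R):
        w = resp[:, r]
        Cr = (r0.T * w) @ r0 / w.sum()
        C.append(Cr + 1e-8 * np.eye(M) + 0.05 * base * rng.uniform(0.5, 1.5))
    pi = np.full(R, 1.0 / R)
    last = -np.inf
    for it in range(max_iter):
        # E-step
        logp = np.empty((L, R))
        chols = []
        for r in range(R):
            try:
                cf = cho_factor(C[r], lower=True)
            except np.linalg.LinAlgError:
                return None
            chols.append(cf)
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            res = d - mu
            quad = np.einsum("lm,lm->l", res, cho_solve(cf, res.T).T)
            logp[:, r] = np.log(pi[r]) - 0.5 * (M * _LOG2PI + logdet + quad)
        mx = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - mx)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float((np.log(tot) + mx).sum())
        # M-step (ECM): pi, then mu by GLS, then C_r by weighted scatter
        nr = resp.sum(axis=0)
        if np.any(nr < M + 1):
            return None  # component collapse -> restart
        pi = nr / L
        num = den = 0.0
        for r in range(R):
            g = cho_solve(chols[r], np.ones(M))
            num += float(g @ (resp[:, r] @ d))
            den += float(nr[r] * g.sum())
        mu = num / den
        res = d - mu
        for r in range(R):
            C[r] = ((res.T * resp[:, r]) @ res) / nr[r] + 1e-10 * np.eye(M)
        if it > 0 and ll - last < tol * (abs(last) + 1.0):
            return pi, C, mu, resp, ll
        last = ll
    return pi, C, mu, resp, last


# ---------------------------------------------------------------------------
# step 3: coercion onto the graph

def _profiled_rss(graph: PopulationGraph, W_targets, pi, rates) -> tuple[float, np.ndarray]:
    """min_c sum_r pi_r ||W_r - W(c, w_r)||_F^2 (c by linear least squares)."""
    R = len(W_targets)
    M, K = graph.M, graph.K
    rows = []
    rhs = []
    for r in range(R):
        P = branch_inclusion_probabilities(graph, rates[r])  # (M, K)
        A = np.empty((M * M, K))
        for k in range(K):
            A[:, k] = np.outer(P[:, k], P[:, k]).ravel()
        wgt = np.sqrt(pi[r])
        rows.append(wgt * A)
        rhs.append(wgt * np.asarray(W_targets[r], float).ravel())
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    # tiny ridge: branch pairs that enter only through their sum (e.g. a
    # split around a closed migration edge) make A rank deficient; the
    # ridge picks the balanced minimum-norm split instead of a huge one
    lam = 1e-8 * max(1.0, float(np.trace(A.T @ A)) / K)
    G = A.T @ A + lam * np.eye(K)
    c = np.linalg.solve(G, A.T @ b)
    resid = A @ c - b
    return float(resid @ resid), c


def coerce_to_graph(W_targets: list[np.ndarray], pi: np.ndarray,
                    graph: PopulationGraph, restarts: int = 1000,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray, float]:
    """Coerce mixture covariances onto the graph.

    Minimizes ``sum_r pi_r || W_r - W(c, w_r) ||_F^2`` over shared branch
    lengths c and per-component rates w_r.  Branch lengths enter W
    linearly and are profiled out exactly; Nelder-Mead (restarted
    ``restarts`` times from uniform random rates on a logit scale)
    handles the rates.  Returns ``(c, w (R, I), weighted RSS)``.
    """
    pi = np.asarray(pi, float)
    R = len(W_targets)
    I = graph.I
    rng = np.random.default_rng(seed)
    if I == 0:
        rss, c = _profiled_rss(graph, W_targets, pi, np.zeros((R, 0)))
        return c, np.zeros((R, 0)), rss

    def objective(x):
        rates = 1.0 / (1.0 + np.exp(-x.reshape(R, I)))
        rss, _ = _profiled_rss(graph, W_targets, pi, rates)
        return rss

    best = (np.inf, None)
    for _ in range(restarts):
        w0 = rng.uniform(0.02, 0.98, size=R * I)
        x0 = np.log(w0 / (1.0 - w0))
        res = scipy.optimize.minimize(objective, x0, method="Nelder-Mead",
                                      options={"maxiter": 400 * R * I,
                                               "xatol": 1e-8, "fatol": 1e-12})
        if res.fun < best[0]:
            best = (res.fun, res.x)
    if best[1] is None:
        warnings.warn("coercion failed to improve over initialization")
        rates = np.full((R, I), 0.5)
    else:
        rates = 1.0 / (1.0 + np.exp(-best[1].reshape(R, I)))
    rss, c = _profiled_rss(graph, W_targets, pi, rates)
    return c, rates, rss


def select_num_components(d: np.ndarray, sigma_bar: np.ndarray,
                          graph: PopulationGraph, config: FitConfig,
                          sigma2: float | None = None
                          ) -> tuple[MixtureInit, np.ndarray, np.ndarray]:
    """Grow R while every pi_r > threshold and the weighted RSS decreases.

    Returns the last accepted mixture together with the coerced branch
    lengths and per-component rates.
    """
    accepted = None
    for R in range(1, config.max_components + 1):
        mix = gmm_em(d, sigma_bar, R, seed=config.seed + R, sigma2=sigma2,
                     tol=config.gmm_tol, max_iter=config.gmm_max_iter)
        if R > 1 and np.any(mix.pi <= config.pi_threshold):
            break
        c, rates, rss = coerce_to_graph(mix.W, mix.pi, graph,
                                        restarts=config.restarts,
                                        seed=config.seed + 77 * R)
        mix.rss = rss
        if accepted is not None and rss >= accepted[0].rss:
            break
        accepted = (mix, c, rates)
    assert accepted is not None
    return accepted


# ---------------------------------------------------------------------------
# Q-function machinery (emission part)

class _EmissionQ:
    """Expected complete-data log-likelihood terms that involve S_{j,u}.

    Built from the E-step posteriors via sufficient statistics
    n_{ju} = sum gamma, m_{ju} = sum gamma d, A_{ju} = sum gamma d d'.
    """

    def __init__(self, graph: PopulationGraph, rates: np.ndarray,
                 clusters: SampleSizeClusters, gamma: np.ndarray,
                 d: np.ndarray) -> None:
        self.graph = graph
        self.rates = np.atleast_2d(rates)
        self.clusters = clusters
        self.M = graph.M
        self.K = graph.K
        S = self.rates.shape[0]
        self.P = [branch_inclusion_probabilities(graph, r) for r in self.rates]
        self.stats = []  # per cluster: (n (S,), m (S,M), A (S,M,M))
        for u in range(clusters.u):
            idx = clusters.assignment == u
            g = gamma[idx]
            du = d[idx]
            n = g.sum(axis=0)
            m = g.T @ du
            A = np.einsum("ls,lm,ln->smn", g, du, du, optimize=True)
            self.stats.append((n, m, A))
        self.n_states = S

    def _S(self, j: int, u: int, c: np.ndarray, sigma2: float) -> np.ndarray:
        P = self.P[j]
        W = (P * c) @ P.T
        return self.clusters.sigma(u) + W + sigma2

    def q(self, c: np.ndarray, mu: float, sigma2: float) -> float:
        total = 0.0
        for u in range(self.clusters.u):
            n, m, A = self.stats[u]
            for j in range(self.n_states):
                if n[j] <= 0:
                    continue
                S = self._S(j, u, c, sigma2)
                try:
                    cf = cho_factor(S, lower=True)
                except np.linalg.LinAlgError:
                    return -np.inf
                logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
                R = A[j] - mu * (np.outer(m[j], np.ones(self.M))
                                 + np.outer(np.ones(self.M), m[j])) \
                    + mu * mu * n[j]
                total += -0.5 * (n[j] * (self.M * _LOG2PI + logdet)
                                 + np.trace(cho_solve(cf, R)))
        return float(total)

    def optimal_mu(self, c: np.ndarray, sigma2: float) -> float:
        num = den = 0.0
        for u in range(self.clusters.u):
            n, m, _ = self.stats[u]
            for j in range(self.n_states):
                if n[j] <= 0:
                    continue
                S = self._S(j, u, c, sigma2)
                try:
                    cf = cho_factor(S, lower=True)
                except np.linalg.LinAlgError:
                    continue
                g = cho_solve(cf, np.ones(self.M))
                num += float(g @ m[j])
                den += float(n[j] * g.sum())
        if den == 0:
            raise RuntimeError("mu update degenerate: no valid emission covariance")
        return num / den

    def dq_dsigma2(self, c: np.ndarray, mu: float, sigma2: float) -> float:
        total = 0.0
        for u in range(self.clusters.u):
            n, m, A = self.stats[u]
            for j in range(self.n_states):
                if n[j] <= 0:
                    continue
                S = self._S(j, u, c, sigma2)
                cf = cho_factor(S, lower=True)
                g = cho_solve(cf, np.ones(self.M))
                R = A[j] - mu * (np.outer(m[j], np.ones(self.M))
                                 + np.outer(np.ones(self.M), m[j])) \
                    + mu * mu * n[j]
                total += 0.5 * (float(g @ R @ g) - n[j] * g.sum())
        return float(total)

    def grad_c(self, c: np.ndarray, mu: float, sigma2: float) -> np.ndarray:
        grad = np.zeros(self.K)
        for u in range(self.clusters.u):
            n, m, A = self.stats[u]
            for j in range(self.n_states):
                if n[j] <= 0:
                    continue
                S = self._S(j, u, c, sigma2)
                cf = cho_factor(S, lower=True)
                H = cho_solve(cf, np.eye(self.M))
                R = A[j] - mu * (np.outer(m[j], np.ones(self.M))
                                 + np.outer(np.ones(self.M), m[j])) \
                    + mu * mu * n[j]
                T = H @ R @ H
                P = self.P[j]
                grad += 0.5 * (np.einsum("mk,mn,nk->k", P, T, P)
                               - n[j] * np.einsum("mk,mn,nk->k", P, H, P))
        return grad


def m_step_root(eq: _EmissionQ, c: np.ndarray, mu: float, sigma2: float,
                max_newton: int = 25) -> tuple[float, float]:
    """Analytic GLS update of mu, then safeguarded Newton for sigma^2.

    sigma^2 is optimized on the log scale (positivity for free); a
    bounded scalar search is the fallback when Newton misbehaves.
    """
    mu = eq.optimal_mu(c, sigma2)
    t = np.log(sigma2)
    q0 = eq.q(c, mu, np.exp(t))
    for _ in range(max_newton):
        s2 = np.exp(t)
        g = eq.dq_dsigma2(c, mu, s2) * s2  # chain rule to log scale
        if abs(g) < 1e-10 * (abs(q0) + 1.0):
            break
        h = 1e-4
        g2 = eq.dq_dsigma2(c, mu, np.exp(t + h)) * np.exp(t + h)
        hess = (g2 - g) / h
        step = -g / hess if hess < 0 else np.sign(g)  # ascent fallback
        step = np.clip(step, -2.0, 2.0)
        accepted = False
        for _ in range(20):
            qn = eq.q(c, mu, np.exp(t + step))
            if np.isfinite(qn) and qn >= q0:
                t, q0, accepted = t + step, qn, True
                break
            step *= 0.5
        if not accepted:
            break
    else:  # Newton budget exhausted: bracketed fallback
        res = scipy.optimize.minimize_scalar(
            lambda tt: float(np.clip(-eq.q(c, mu, np.exp(tt)), -1e30, 1e30)),
            bounds=(t - 5, t + 5), method="bounded")
        if -res.fun > q0:
            t = res.x
    return float(mu), float(np.exp(t))


def m_step_branch_lengths(eq: _EmissionQ, c: np.ndarray, mu: float,
                          sigma2: float, max_newton: int = 12) -> np.ndarray:
    """Safeguarded Newton-Raphson ascent of the Q-function over c.

    Gradient is analytic (rank-one dS/dc_k = p_k p_k'); the Hessian is
    a finite difference of the gradient.  Steps are halved on any Q
    decrease; an indefinite Hessian falls back to a gradient step.
    Branch lengths are unconstrained in sign.
    """
    c = np.asarray(c, float).copy()
    q0 = eq.q(c, mu, sigma2)
    K = len(c)
    for _ in range(max_newton):
        g = eq.grad_c(c, mu, sigma2)
        gnorm = np.linalg.norm(g)
        if gnorm < 1e-9 * (abs(q0) + 1.0):
            break
        h = 1e-6 * (np.abs(c) + 1e-3)
        H = np.empty((K, K))
        for k in range(K):
            ck = c.copy()
            ck[k] += h[k]
            H[:, k] = (eq.grad_c(ck, mu, sigma2) - g) / h[k]
        H = 0.5 * (H + H.T)
        try:
            vals = np.linalg.eigvalsh(H)
            # Levenberg damping: near-flat directions (e.g. a branch split
            # whose lengths only enter through their sum) otherwise launch
            # unbounded steps at unchanged Q
            lam = max(0.0, vals.max()) + 1e-6 * max(1.0, -vals.min())
            step = -np.linalg.solve(H - lam * np.eye(K), g)
        except np.linalg.LinAlgError:
            step = g / max(gnorm, 1.0) * 0.05
        cap = 0.5 + 2.0 * np.abs(c)
        over = np.abs(step) / cap
        if over.max() > 1.0:
            step = step / over.max()
        accepted = False
        for _ in range(25):
            qn = eq.q(c + step, mu, sigma2)
            if np.isfinite(qn) and qn > q0 + 1e-10 * (abs(q0) + 1.0):
                c, q0, accepted = c + step, qn, True
                break
            step *= 0.5
        if not accepted:
            break
    return c


def m_step_transition(xi_by_edge, first_gamma_by_edge, grids: MigrationGrid,
                      variant: str, kappa: np.ndarray,
                      phi: np.ndarray | None = None,
                      zeta: np.ndarray | None = None,
                      attractor: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Per-edge transition-parameter update from expected transition counts.

    Ladder: bounded line search for kappa on the log scale (bracket
    expanded when the optimum hits a boundary).  Attractor: Nelder-Mead
    over (log kappa, logit phi, logit zeta); the stationary initial-law
    term is included since it depends on phi and zeta.
    """
    I = grids.I
    kappa = np.atleast_1d(np.array(kappa, float, copy=True))
    phi_out = None if phi is None else np.atleast_1d(np.array(phi, float, copy=True))
    zeta_out = None if zeta is None else np.atleast_1d(np.array(zeta, float, copy=True))

    def q_edge(i, kap, ph=None, ze=None):
        J = grids.J[i]
        if J == 1:
            return 0.0
        if not np.isfinite(kap) or kap <= 0:
            return -1e30
        if variant == "ladder":
            sub = TransitionModel("ladder", MigrationGrid([grids.grids[i]]), [kap])
        else:
            sub = TransitionModel("attractor", MigrationGrid([grids.grids[i]]),
                                  [kap], np.array([ph]), np.array([ze]),
                                  np.array([int(attractor[i])]))
        total = 0.0
        try:
            for dl, xi in xi_by_edge[i].items():
                P = sub.edges[0].P(dl)
                total += float(np.sum(xi * np.log(np.clip(P, 1e-300, None))))
        except ValueError:
            return -1e30
        pi0 = sub.edges[0].pi
        total += float(first_gamma_by_edge[i] @ np.log(np.clip(pi0, 1e-300, None)))
        return total if np.isfinite(total) else -1e30

    for i in range(I):
        if grids.J[i] == 1 or not xi_by_edge[i]:
            continue
        if variant == "ladder":
            t0 = np.log(kappa[i])
            lo, hi = t0 - 6.0, t0 + 6.0
            for _ in range(4):  # expand the bracket if the optimum sits on it
                res = scipy.optimize.minimize_scalar(
                    lambda t: -q_edge(i, np.exp(t)), bounds=(lo, hi),
                    method="bounded", options={"xatol": 1e-6})
                if res.x - lo < 0.05:
                    lo -= 6.0
                elif hi - res.x < 0.05:
                    hi += 6.0
                else:
                    break
            else:
                warnings.warn("kappa line search ended on an expanded bracket boundary")
            if -res.fun >= q_edge(i, kappa[i]):
                kappa[i] = float(np.exp(res.x))
        else:
            def logit(p):
                p = np.clip(p, 1e-6, 1 - 1e-6)
                return np.log(p / (1 - p))

            x0 = np.array([np.log(kappa[i]), logit(phi_out[i]), logit(zeta_out[i])])

            def obj(x):
                kap = np.exp(np.clip(x[0], -20, 20))
                ph = float(np.clip(1.0 / (1.0 + np.exp(-x[1])), 1e-12, 1.0))
                ze = float(np.clip(1.0 / (1.0 + np.exp(-x[2])), 1e-12, 1.0))
                return -q_edge(i, kap, ph, ze)

            res = scipy.optimize.minimize(obj, x0, method="Nelder-Mead",
                                          options={"maxiter": 400, "xatol": 1e-6,
                                                   "fatol": 1e-9})
            if -res.fun >= -obj(x0):
                kappa[i] = float(np.exp(np.clip(res.x[0], -20, 20)))
                phi_out[i] = float(np.clip(1.0 / (1.0 + np.exp(-res.x[1])), 1e-12, 1.0))
                zeta_out[i] = float(np.clip(1.0 / (1.0 + np.exp(-res.x[2])), 1e-12, 1.0))
    return kappa, phi_out, zeta_out


# ---------------------------------------------------------------------------
# Baum-Welch with SQUAREM

class _FitContext:
    """Static quantities shared by every Baum-Welch iteration."""

    def __init__(self, dataset: AlleleCountDataset, graph: PopulationGraph,
                 space: HiddenStateSpace, clusters: SampleSizeClusters) -> None:
        self.dataset = dataset
        self.graph = graph
        self.space = space
        self.clusters = clusters
        self.delta, self.rescale = dataset.rescaled_distances()
        self.starts = dataset.chromosome_starts()


def _pack(c, mu, sigma2, kappa, phi, zeta):
    parts = [c, [mu], [np.log(sigma2)], np.log(kappa)]
    if phi is not None:
        p = np.clip(phi, 1e-6, 1 - 1e-6)
        z = np.clip(zeta, 1e-6, 1 - 1e-6)
        parts += [np.log(p / (1 - p)), np.log(z / (1 - z))]
    return np.concatenate([np.atleast_1d(np.asarray(x, float)) for x in parts])


def _unpack(theta, K, I, has_attractor):
    c = theta[:K]
    mu = float(theta[K])
    sigma2 = float(np.exp(np.clip(theta[K + 1], -40, 40)))
    kappa = np.exp(np.clip(theta[K + 2:K + 2 + I], -40, 40))
    phi = zeta = None
    if has_attractor:
        phi = np.clip(1.0 / (1.0 + np.exp(-theta[K + 2 + I:K + 2 + 2 * I])), 1e-12, 1.0)
        zeta = np.clip(1.0 / (1.0 + np.exp(-theta[K + 2 + 2 * I:K + 2 + 3 * I])), 1e-12, 1.0)
    return c, mu, sigma2, kappa, phi, zeta


def _e_step(ctx: _FitContext, variant, theta, attractor, collect_xi=True):
    K, I = ctx.graph.K, ctx.space.grid.I
    c, mu, sigma2, kappa, phi, zeta = _unpack(theta, K, I, variant == "attractor")
    model = TransitionModel(variant, ctx.space.grid, kappa, phi, zeta, attractor)
    table = EmissionTable(ctx.graph, c, ctx.space.rates, ctx.clusters, mu, sigma2)
    log_e = table.log_emissions(ctx.dataset)
    fb = forward_backward(log_e, model, ctx.delta, ctx.starts, collect_xi=collect_xi)
    return fb, model


def _marginal_first_gamma(first_gamma, grid: MigrationGrid):
    I = grid.I
    J = grid.J
    t = first_gamma.reshape(J)
    out = []
    for i in range(I):
        axes = tuple(k for k in range(I) if k != i)
        out.append(t.sum(axis=axes) if I > 1 else t.copy())
    return out


def _m_step(ctx: _FitContext, variant, theta, attractor, fb: ForwardBackwardResult):
    K, I = ctx.graph.K, ctx.space.grid.I
    c, mu, sigma2, kappa, phi, zeta = _unpack(theta, K, I, variant == "attractor")
    eq = _EmissionQ(ctx.graph, ctx.space.rates, ctx.clusters, fb.gamma, ctx.dataset.d)
    # partial conditional maximization per EM sweep (GEM keeps monotonicity)
    mu, sigma2 = m_step_root(eq, c, mu, sigma2, max_newton=8)
    c = m_step_branch_lengths(eq, c, mu, sigma2, max_newton=4)
    mu, sigma2 = m_step_root(eq, c, mu, sigma2, max_newton=4)
    fg = _marginal_first_gamma(fb.first_gamma, ctx.space.grid)
    kappa, phi, zeta = m_step_transition(fb.xi_by_edge, fg, ctx.space.grid,
                                         variant, kappa, phi, zeta, attractor)
    return _pack(c, mu, sigma2, kappa, phi, zeta)


def baum_welch(dataset: AlleleCountDataset, graph: PopulationGraph,
               space: HiddenStateSpace, variant: str, *,
               c0: np.ndarray, mu0: float, sigma20: float,
               kappa0: np.ndarray, phi0: np.ndarray | None = None,
               zeta0: np.ndarray | None = None,
               attractor: np.ndarray | None = None,
               config: FitConfig | None = None,
               clusters: SampleSizeClusters | None = None) -> FittedModel:
    """EM over (c, mu, sigma^2, transition parameters) with SQUAREM.

    Each outer round takes two plain EM steps, forms the squared
    extrapolation, and keeps it only if it does not lower the
    likelihood; plain EM steps that *decrease* the likelihood beyond
    numerical tolerance abort with a diagnostic (they indicate an
    M-step bug, not data trouble).
    """
    config = config or FitConfig()
    clusters = clusters or cluster_sample_sizes(dataset.N, config.sigma_clusters)
    ctx = _FitContext(dataset, graph, space, clusters)
    if variant == "attractor" and (phi0 is None or zeta0 is None or attractor is None):
        raise ValueError("attractor variant requires phi0, zeta0 and attractor indices")
    theta = _pack(c0, mu0, sigma20, kappa0,
                  phi0 if variant == "attractor" else None,
                  zeta0 if variant == "attractor" else None)

    def em(th):
        fb, _ = _e_step(ctx, variant, th, attractor)
        return _m_step(ctx, variant, th, attractor, fb), fb.loglik

    def ll_only(th):
        try:
            fb, _ = _e_step(ctx, variant, th, attractor, collect_xi=False)
            return fb.loglik
        except (ValueError, np.linalg.LinAlgError):
            return -np.inf

    trace: list[float] = []
    prev_ll = -np.inf
    n_em = 0
    converged = False
    while n_em < config.max_iter:
        theta1, ll0 = em(theta)
        n_em += 1
        if trace and ll0 < trace[-1] - 1e-8 * (abs(trace[-1]) + 1.0):
            raise RuntimeError(
                f"likelihood decreased on a plain EM step ({trace[-1]:.8f} -> {ll0:.8f})")
        trace.append(ll0)
        if np.isfinite(prev_ll) and abs(ll0 - prev_ll) < config.tol * (abs(prev_ll) + 1.0):
            converged = True
            theta = theta1
            break
        prev_ll = ll0
        if not config.squarem:
            theta = theta1
            continue
        theta2, ll1 = em(theta1)
        n_em += 1
        trace.append(ll1)
        r = theta1 - theta
        v = theta2 - theta1 - r
        vv = float(v @ v)
        if vv < 1e-30:
            theta = theta2
            continue
        alpha = -np.sqrt(float(r @ r) / vv)
        alpha = min(alpha, -1.0)
        theta_sq = theta - 2.0 * alpha * r + alpha * alpha * v
        ll_sq = ll_only(theta_sq)
        ll_t2 = ll_only(theta2)
        theta = theta_sq if ll_sq >= ll_t2 else theta2
    final_ll = ll_only(theta)
    trace.append(final_ll)
    K, I = graph.K, space.grid.I
    c, mu, sigma2, kappa, phi, zeta = _unpack(theta, K, I, variant == "attractor")
    return FittedModel(
        graph=graph.with_branch_lengths(c), c=c, mu=mu, sigma2=sigma2,
        variant=variant, kappa=kappa, phi=phi, zeta=zeta,
        attractor=None if attractor is None else np.asarray(attractor, int),
        grid=space.grid, loglik=final_ll, n_iter=n_em, converged=converged,
        negative_branch_lengths=bool(np.any(c < 0)),
        distance_rescale=ctx.rescale, trace=trace,
    )


def attractor_search(dataset: AlleleCountDataset, graph: PopulationGraph,
                     space: HiddenStateSpace, ladder_fit: FittedModel,
                     config: FitConfig,
                     clusters: SampleSizeClusters | None = None) -> FittedModel:
    """Try the top-T mean-posterior states as attractors; keep the best model.

    Branch lengths and priors are re-optimized inside each candidate
    run (warm-started from the ladder fit).  Returns the ladder fit
    itself when no attractor candidate beats its likelihood.
    """
    clusters = clusters or cluster_sample_sizes(dataset.N, config.sigma_clusters)
    ctx = _FitContext(dataset, graph, space, clusters)
    theta = _pack(ladder_fit.c, ladder_fit.mu, ladder_fit.sigma2,
                  ladder_fit.kappa, None, None)
    fb, _ = _e_step(ctx, "ladder", theta, None, collect_xi=False)
    mean_post = fb.gamma.mean(axis=0)
    T = min(config.top_states, space.n_states)
    candidates = np.argsort(mean_post)[::-1][:T]
    best = ladder_fit
    for state in candidates:
        a = space.multi_index[state]
        try:
            cand = baum_welch(
                dataset, graph, space, "attractor",
                c0=ladder_fit.c, mu0=ladder_fit.mu, sigma20=ladder_fit.sigma2,
                kappa0=ladder_fit.kappa,
                phi0=np.full(space.grid.I, 0.5), zeta0=np.full(space.grid.I, 0.5),
                attractor=np.asarray(a, int), config=config, clusters=clusters)
        except RuntimeError:
            continue
        if cand.loglik > best.loglik:
            best = cand
    return best


# ---------------------------------------------------------------------------
# orchestration

def fit(dataset: AlleleCountDataset, graph: PopulationGraph,
        config: FitConfig | None = None, *,
        ladder_only: bool = False) -> tuple[FittedModel, PosteriorSummary]:
    """Full empirical-Bayes pipeline: init -> ladder Baum-Welch ->
    attractor search -> posterior decoding.  Deterministic given
    ``config.seed``."""
    import logging

    log = logging.getLogger("locusmix")
    config = config or FitConfig()
    if not config.keep_monomorphic:
        dataset = dataset.drop_monomorphic()
    if dataset.L < dataset.M + 1:
        raise ValueError("too few informative loci")
    log.info("fit: %d loci, %d populations, %d migration edge(s)",
             dataset.L, dataset.M, graph.I)
    clusters = cluster_sample_sizes(dataset.N, config.sigma_clusters)
    sigma2_0 = moment_sigma2(dataset.d)
    mix, c0, _rates = select_num_components(
        dataset.d, clusters.mean_sigma(), graph, config, sigma2=sigma2_0)
    log.info("mixture init: R=%d, coercion RSS=%.3g", mix.R, mix.rss)
    grid = MigrationGrid([uniform_grid(config.grid_size) for _ in range(graph.I)])
    space = HiddenStateSpace(grid)
    delta, _ = dataset.rescaled_distances()
    mean_delta = float(np.nanmean(delta)) if np.any(np.isfinite(delta)) else 1.0
    kappa0 = np.full(graph.I, 1.0 / mean_delta)
    ladder = baum_welch(dataset, graph, space, "ladder",
                        c0=c0, mu0=mix.mu, sigma20=mix.sigma2,
                        kappa0=kappa0, config=config, clusters=clusters)
    log.info("ladder fit: loglik=%.4f after %d EM steps (converged=%s)",
             ladder.loglik, ladder.n_iter, ladder.converged)
    model = ladder if (ladder_only or graph.I == 0) else attractor_search(
        dataset, graph, space, ladder, config, clusters=clusters)
    log.info("final model: %s, loglik=%.4f", model.variant, model.loglik)
    ctx = _FitContext(dataset, graph, space, clusters)
    theta = _pack(model.c, model.mu, model.sigma2, model.kappa,
                  model.phi, model.zeta)
    fb, tmodel = _e_step(ctx, model.variant, theta, model.attractor,
                         collect_xi=False)
    summary = posterior_summaries(fb.gamma, space, model.attractor,
                                  loglik=fb.loglik, model=tmodel)
    return model, summary
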