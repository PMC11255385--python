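"""Hidden Markov machinery over discretized migration rates.

Hidden states are multi-indices over per-edge migration-rate grids.
Each edge evolves independently along the genome as a continuous-time
Markov chain with rate matrix kappa_i * Lambda_i, integrated over the
inter-locus distance delta_l, so the per-locus transition matrix is
P = exp(delta * kappa * Lambda) and the joint transition factorizes over
edges.  Two infinitesimal models are supported: a symmetric *ladder*
(nearest-neighbour moves at unit rate) and an *attractor* ladder whose
chain drifts toward a distinguished background state a at rate 1 + zeta,
away at 1 - zeta, and leaves the attractor itself at rate phi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import reduce

import numpy as np
import scipy.linalg

__all__ = [
    "MigrationGrid",
    "HiddenStateSpace",
    "rate_matrix",
    "stationary_distribution",
    "EdgeTransition",
    "TransitionModel",
    "joint_transition",
    "apply_factorized",
    "forward_backward",
    "ForwardBackwardResult",
    "PosteriorSummary",
    "posterior_summaries",
    "uniform_grid",
]


def uniform_grid(J: int) -> np.ndarray:
    """J equally spaced rates spanning [0, 1] (default grid)."""
    return np.linspace(0.0, 1.0, J)


@dataclass
class MigrationGrid:
    """Ordered rate grids, one per migration edge."""

    grids: list[np.ndarray]

    def __post_init__(self) -> None:
        self.grids = [np.asarray(g, float) for g in self.grids]
        for g in self.grids:
            if g.ndim != 1 or np.any(np.diff(g) <= 0):
                raise ValueError("grid rates must be strictly increasing")
            if np.any((g < 0) | (g > 1)):
                raise ValueError("grid rates must lie in [0, 1]")

    @property
    def I(self) -> int:
        return len(self.grids)

    @property
    def J(self) -> list[int]:
        return [len(g) for g in self.grids]


@dataclass
class HiddenStateSpace:
    """Bijection between linear state indices and per-edge multi-indices."""

    grid: MigrationGrid
    multi_index: np.ndarray = field(init=False)  # (n_states, I)
    rates: np.ndarray = field(init=False)        # (n_states, I)

    def __post_init__(self) -> None:
        J = self.grid.J
        if not J:  # migration-free graph: a single (empty) state
            self.multi_index = np.zeros((1, 0), int)
            self.rates = np.zeros((1, 0))
            return
        self.multi_index = np.array(list(np.ndindex(*J)), int).reshape(-1, len(J))
        self.rates = np.column_stack(
            [self.grid.grids[i][self.multi_index[:, i]] for i in range(len(J))]
        )

    @property
    def n_states(self) -> int:
        return self.multi_index.shape[0]

    def linear_index(self, multi: tuple[int, ...]) -> int:
        return int(np.ravel_multi_index(multi, self.grid.J))


# ---------------------------------------------------------------------------
# rate matrices

def rate_matrix(J: int, variant: str = "ladder", phi: float | None = None,
                zeta: float | None = None, a: int | None = None) -> np.ndarray:
    """Infinitesimal rate matrix Lambda for one edge's grid of size J.

    ``variant="ladder"``: tridiagonal, boundary rows (-1, 1)/(1, -1),
    interior rows (1, -2, 1).

    ``variant="attractor"``: requires ``phi, zeta in (0, 1]`` and a grid
    index ``a`` (0-based).  Interior rows move toward the attractor at
    rate 1 + zeta and away at 1 - zeta; the attractor row is
    (..., phi, -2*phi, phi, ...); boundary rows keep unit rates, except
    an attractor at a boundary which becomes (-phi, phi) / (phi, -phi).
    """
    if J < 2:
        raise ValueError("grid size must be >= 2")
    L = np.zeros((J, J))
    if variant == "ladder":
        for i in range(J):
            if i > 0:
                L[i, i - 1] = 1.0
            if i < J - 1:
                L[i, i + 1] = 1.0
            L[i, i] = -(L[i].sum())
        return L
    if variant != "attractor":
        raise ValueError(f"unknown transition variant {variant!r}")
    if phi is None or zeta is None or a is None:
        raise ValueError("attractor variant requires phi, zeta and a")
    if not (0.0 < phi <= 1.0 and 0.0 < zeta <= 1.0):
        raise ValueError("phi and zeta must lie in (0, 1]")
    if not (0 <= a < J):
        raise ValueError("bad attractor index")
    for i in range(J):
        if i == a:
            if i > 0:
                L[i, i - 1] = phi
            if i < J - 1:
                L[i, i + 1] = phi
        elif i in (0, J - 1):
            if i > 0:
                L[i, i - 1] = 1.0
            if i < J - 1:
                L[i, i + 1] = 1.0
        elif i < a:
            L[i, i - 1] = 1.0 - zeta  # away from the attractor
            L[i, i + 1] = 1.0 + zeta  # toward the attractor
        else:
            L[i, i - 1] = 1.0 + zeta
            L[i, i + 1] = 1.0 - zeta
        L[i, i] = -(L[i].sum())
    return L


def stationary_distribution(L: np.ndarray) -> np.ndarray:
    """Stationary law of a tridiagonal (birth-death) rate matrix.

    Uses detailed balance pi_{i+1}/pi_i = L[i,i+1]/L[i+1,i] when all
    inner rates are positive; otherwise solves the left null space.
    """
    J = L.shape[0]
    up = np.array([L[i, i + 1] for i in range(J - 1)])
    dn = np.array([L[i + 1, i] for i in range(J - 1)])
    if np.all(up > 0) and np.all(dn > 0):
        logpi = np.concatenate([[0.0], np.cumsum(np.log(up) - np.log(dn))])
        logpi -= logpi.max()
        pi = np.exp(logpi)
    else:
        vals, vecs = scipy.linalg.eig(L.T)
        k = int(np.argmin(np.abs(vals)))
        pi = np.abs(np.real(vecs[:, k]))
    return pi / pi.sum()


class EdgeTransition:
    """One edge's CTMC: P(delta) = exp(delta * kappa * Lambda), cached.

    The tridiagonal Lambda is reversible, so when all off-diagonals are
    positive it is symmetrized by the stationary square root and
    diagonalized once; each distance then costs one O(J^2) congruence.
    Degenerate chains (a zero rate, e.g. zeta = 1) fall back to
    ``scipy.linalg.expm`` per distance.
    """

    def __init__(self, L: np.ndarray, kappa: float) -> None:
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        self.L = np.asarray(L, float)
        self.kappa = float(kappa)
        self.J = L.shape[0]
        self.pi = stationary_distribution(self.L)
        self._cache: dict[float, np.ndarray] = {}
        self._eig = None
        if np.all(self.pi > 0):
            s = np.sqrt(self.pi)
            A = (s[:, None] * self.L) / s[None, :]
            if np.allclose(A, A.T, atol=1e-10):
                vals, Q = np.linalg.eigh(0.5 * (A + A.T))
                self._eig = (vals, Q, s)

    def P(self, delta: float) -> np.ndarray:
        delta = float(delta)
        if delta <= 0:
            raise ValueError("inter-locus distance must be positive")
        hit = self._cache.get(delta)
        if hit is not None:
            return hit
        t = delta * self.kappa
        if self._eig is not None:
            vals, Q, s = self._eig
            core = (Q * np.exp(vals * t)) @ Q.T
            P = (core / s[:, None]) * s[None, :]
        else:
            P = scipy.linalg.expm(t * self.L)
        if not np.all(np.isfinite(P)):
            raise ValueError("transition failure: non-finite transition matrix")
        P = np.clip(P, 0.0, None)
        rows = P.sum(axis=1, keepdims=True)
        if np.any(rows <= 0):  # total underflow at extreme kappa*delta
            raise ValueError("transition failure: degenerate transition matrix")
        P /= rows
        self._cache[delta] = P
        return P


def transition_matrix(L: np.ndarray, kappa: float, delta: float) -> np.ndarray:
    """P = exp(delta * kappa * Lambda) as a row-stochastic matrix."""
    return EdgeTransition(L, kappa).P(delta)


@dataclass
class TransitionModel:
    """Per-edge transition parameters and cached per-edge chains."""

    variant: str                  # "ladder" or "attractor"
    grids: MigrationGrid
    kappa: np.ndarray             # (I,)
    phi: np.ndarray | None = None
    zeta: np.ndarray | None = None
    attractor: np.ndarray | None = None  # (I,) 0-based grid indices

    def __post_init__(self) -> None:
        self.kappa = np.atleast_1d(np.asarray(self.kappa, float))
        self.edges = []
        for i, J in enumerate(self.grids.J):
            if J == 1:  # degenerate single-rate edge: frozen chain
                L = np.zeros((1, 1))
            elif self.variant == "ladder":
                L = rate_matrix(J, "ladder")
            else:
                L = rate_matrix(
                    J, "attractor", float(self.phi[i]), float(self.zeta[i]),
                    int(self.attractor[i]),
                )
            self.edges.append(EdgeTransition(L, float(self.kappa[i])))
        self._joint_cache: dict[float, np.ndarray] = {}

    @property
    def I(self) -> int:
        return len(self.edges)

    def initial_distribution(self) -> np.ndarray:
        """Product of the per-edge stationary laws (chain start at each chromosome)."""
        if not self.edges:
            return np.ones(1)
        return reduce(np.kron, [e.pi for e in self.edges])

    def joint_P(self, delta: float) -> np.ndarray:
        if not self.edges:
            return np.ones((1, 1))
        hit = self._joint_cache.get(float(delta))
        if hit is None:
            hit = joint_transition([e.P(delta) for e in self.edges])
            self._joint_cache[float(delta)] = hit
        return hit


def joint_transition(per_edge_P: list[np.ndarray]) -> np.ndarray:
    """Joint stochastic matrix over the product state space (Kronecker product)."""
    for P in per_edge_P:
        if P.shape[0] != P.shape[1]:
            raise ValueError("dimension mismatch: transition matrices must be square")
    return reduce(np.kron, per_edge_P)


def apply_factorized(per_edge_P: list[np.ndarray], v: np.ndarray,
                     transpose: bool = False) -> np.ndarray:
    """Multiply v by the joint transition without materializing it.

    Computes ``v @ P_joint`` (or ``P_joint @ v`` with ``transpose``) by
    contracting one edge axis at a time on the reshaped tensor.
    """
    J = [P.shape[0] for P in per_edge_P]
    t = np.asarray(v, float).reshape(J)
    for i, P in enumerate(per_edge_P):
        mat = P.T if not transpose else P
        t = np.moveaxis(np.tensordot(mat, np.moveaxis(t, i, 0), axes=(1, 0)), 0, i)
    return t.reshape(-1)


# ---------------------------------------------------------------------------
# forward-backward

@dataclass
class ForwardBackwardResult:
    gamma: np.ndarray                 # (L, S) state posteriors
    loglik: float
    xi_by_edge: list[dict[float, np.ndarray]]  # per edge: {delta: (J, J) expected transitions}
    first_gamma: np.ndarray           # summed state posterior at chain starts


def forward_backward(log_e: np.ndarray, model: TransitionModel, delta: np.ndarray,
                     chrom_starts: np.ndarray,
                     initial: np.ndarray | None = None,
                     collect_xi: bool = True) -> ForwardBackwardResult:
    """Scaled forward-backward over independent per-chromosome chains.

    Parameters
    ----------
    log_e : (L, S) log emission densities (finite or -inf).
    delta : (L,) rescaled inter-locus distances; entries at chromosome
        starts are ignored (chains restart with the initial law there).
    chrom_starts : indices beginning each independent chain.
    initial : initial distribution; defaults to the model's stationary law.

    Returns per-locus posteriors, the total log-likelihood (sum over
    chromosomes) and, per migration edge, expected transition counts
    aggregated by distance value for the transition M-step.
    """
    L, S = log_e.shape
    Jlist = model.grids.J
    init = model.initial_distribution() if initial is None else np.asarray(initial, float)
    gamma = np.empty((L, S))
    xi_by_edge: list[dict[float, np.ndarray]] = [dict() for _ in range(model.I)]
    first_gamma = np.zeros(S)
    loglik = 0.0

    starts = list(chrom_starts) + [L]
    for ci in range(len(starts) - 1):
        s, e = starts[ci], starts[ci + 1]
        n = e - s
        shift = np.max(log_e[s:e], axis=1)
        if np.any(~np.isfinite(shift)):
            bad = s + int(np.argmin(np.isfinite(shift)))
            raise ValueError(f"impossible datum at locus {bad}")
        w = np.exp(log_e[s:e] - shift[:, None])
        alpha = np.empty((n, S))
        scale = np.empty(n)
        a = init * w[0]
        scale[0] = a.sum()
        alpha[0] = a / scale[0]
        for t in range(1, n):
            P = model.joint_P(delta[s + t])
            a = (alpha[t - 1] @ P) * w[t]
            scale[t] = a.sum()
            if scale[t] <= 0:
                raise ValueError(f"impossible datum at locus {s + t}")
            alpha[t] = a / scale[t]
        beta = np.empty((n, S))
        beta[n - 1] = 1.0
        for t in range(n - 2, -1, -1):
            P = model.joint_P(delta[s + t + 1])
            beta[t] = (P @ (w[t + 1] * beta[t + 1])) / scale[t + 1]
        g = alpha * beta
        g /= g.sum(axis=1, keepdims=True)
        gamma[s:e] = g
        first_gamma += g[0]
        loglik += float(np.log(scale).sum() + shift.sum())
        if collect_xi and model.I > 0 and n > 1:
            # expected transition counts, batched over loci sharing a distance
            shape2 = Jlist + Jlist
            ts = np.arange(1, n)
            dls = delta[s + 1:e]
            for dl in np.unique(dls):
                sel = ts[np.isclose(dls, dl)]
                P = model.joint_P(float(dl))
                right = (w[sel] * beta[sel]) / scale[sel, None]
                xi_sum = (alpha[sel - 1].T @ right) * P
                xt = xi_sum.reshape(shape2)
                for i in range(model.I):
                    axes_from = tuple(k for k in range(model.I) if k != i)
                    axes_to = tuple(model.I + k for k in range(model.I) if k != i)
                    m = xt.sum(axis=axes_from + axes_to) if model.I > 1 else xt
                    acc = xi_by_edge[i].get(float(dl))
                    if acc is None:
                        xi_by_edge[i][float(dl)] = m.copy()
                    else:
                        acc += m
    return ForwardBackwardResult(gamma, loglik, xi_by_edge, first_gamma)


# ---------------------------------------------------------------------------
# posterior summaries

@dataclass
class PosteriorSummary:
    """Per-locus posterior summaries, marginalized per migration edge."""

    state_posteriors: np.ndarray      # (L, S)
    loglik: float
    mean_rate: np.ndarray             # (L, I) posterior mean migration w-bar
    q_excess: np.ndarray              # (L, I) FDR score for excess introgression
    q_dearth: np.ndarray              # (L, I) FDR score for dearth
    map_state: np.ndarray             # (L,) linear MAP state index
    attractor: np.ndarray             # (I,) attractor (or surrogate) grid index
    attractor_is_surrogate: bool = False


def posterior_summaries(gamma: np.ndarray, space: HiddenStateSpace,
                        attractor: np.ndarray | None, loglik: float = np.nan,
                        model: TransitionModel | None = None) -> PosteriorSummary:
    """Posterior mean rates and excess/dearth FDR scores per edge.

    ``q_e(l) = 1 - P(z_l > a) = P(z_l <= a)`` and ``q_d(l) = P(z_l >= a)``
    on each edge's marginal chain.  For ladder fits (no attractor) the
    surrogate attractor is the state of highest stationary probability,
    ties broken by the highest mean posterior across loci, and the
    result is flagged as a surrogate.
    """
    L = gamma.shape[0]
    I = space.grid.I
    Jlist = space.grid.J
    gt = gamma.reshape([L] + Jlist)
    mean_rate = np.empty((L, I))
    q_e = np.empty((L, I))
    q_d = np.empty((L, I))
    surrogate = attractor is None
    attr = np.empty(I, int)
    for i in range(I):
        axes = tuple(1 + k for k in range(I) if k != i)
        marg = gt.sum(axis=axes) if I > 1 else gt.reshape(L, Jlist[0])
        grid = space.grid.grids[i]
        mean_rate[:, i] = marg @ grid
        if surrogate:
            if model is not None:
                pi = model.edges[i].pi
            else:
                pi = np.full(Jlist[i], 1.0 / Jlist[i])
            best = np.flatnonzero(pi >= pi.max() - 1e-12)
            if len(best) > 1:
                mean_post = marg.mean(axis=0)
                a_i = int(best[np.argmax(mean_post[best])])
            else:
                a_i = int(best[0])
        else:
            a_i = int(np.atleast_1d(attractor)[i])
        attr[i] = a_i
        cum = np.cumsum(marg, axis=1)
        q_e[:, i] = cum[:, a_i]                                  # P(z <= a)
        q_d[:, i] = 1.0 - (cum[:, a_i - 1] if a_i > 0 else 0.0)  # P(z >= a)
    map_state = np.argmax(gamma, axis=1)
    return PosteriorSummary(gamma, loglik, mean_rate, q_e, q_d, map_state,
                            attr, attractor_is_surrogate=surrogate)
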