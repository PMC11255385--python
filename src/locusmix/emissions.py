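"""Gaussian emission model on the arcsine scale.

The marginal likelihood of the transformed observed frequencies d_l at a
locus in hidden state j is N(mu * 1, S) with

    S = Sigma_u + W(c, w_j) + sigma^2 * 11',

where Sigma_u = diag(1/N) is the (clustered) sampling covariance, W the
drift covariance for the state's migration rates, and (mu, sigma^2) the
root prior on the transformed ancestral frequency.  Because both W and
the set of distinct Sigma_u are finite, all S and their factorizations
are precomputed once per Baum-Welch iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data import AlleleCountDataset
from .graph import PopulationGraph, drift_covariance

__all__ = [
    "SampleSizeClusters",
    "cluster_sample_sizes",
    "marginal_covariance",
    "log_emission",
    "EmissionTable",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class SampleSizeClusters:
    """Representative sample-size vectors and per-locus assignment."""

    representatives: np.ndarray  # (u, M) weighted-average totals
    counts: np.ndarray           # (u,) locus counts per representative
    assignment: np.ndarray       # (L,) cluster index per locus

    @property
    def u(self) -> int:
        return len(self.counts)

    def sigma(self, k: int) -> np.ndarray:
        """Diagonal sampling covariance diag(1/N) for cluster ``k``."""
        return np.diag(1.0 / self.representatives[k])

    def mean_sigma(self) -> np.ndarray:
        """Occurrence-weighted mean sampling matrix (used by the GMM init)."""
        inv = (self.counts[:, None] / self.representatives).sum(axis=0) / self.counts.sum()
        return np.diag(inv)


def cluster_sample_sizes(N: np.ndarray, target_u: int) -> SampleSizeClusters:
    """Greedily merge sample-size vectors until at most ``target_u`` remain.

    Repeatedly takes the two least-frequent distinct total-count vectors
    and replaces them by their occurrence-weighted average with summed
    counts.  Ties on frequency are broken by merging the
    lexicographically smallest pair, which makes the reduction
    deterministic.
    """
    if target_u < 1:
        raise ValueError("target cluster count must be >= 1")
    N = np.asarray(N, float)
    L = N.shape[0]
    uniq, inverse, counts = np.unique(N, axis=0, return_inverse=True, return_counts=True)
    vecs = [tuple(v) for v in uniq]
    cnts = list(counts.astype(float))
    members: list[list[int]] = [[k] for k in range(len(vecs))]  # original uniq rows
    while len(vecs) > target_u:
        order = sorted(range(len(vecs)), key=lambda k: (cnts[k], vecs[k]))
        a, b = order[0], order[1]
        wa, wb = cnts[a], cnts[b]
        merged = tuple(
            (wa * np.array(vecs[a]) + wb * np.array(vecs[b])) / (wa + wb)
        )
        keep = [k for k in range(len(vecs)) if k not in (a, b)]
        vecs = [vecs[k] for k in keep] + [merged]
        cnts = [cnts[k] for k in keep] + [wa + wb]
        members = [members[k] for k in keep] + [members[a] + members[b]]
    reps = np.array(vecs, float)
    cluster_of_uniq = np.empty(len(uniq), int)
    for ci, mem in enumerate(members):
        for k in mem:
            cluster_of_uniq[k] = ci
    assignment = cluster_of_uniq[inverse]
    assert assignment.shape == (L,)
    return SampleSizeClusters(reps, np.array(cnts), assignment)


def marginal_covariance(W: np.ndarray, sigma_u: np.ndarray, sigma2: float) -> np.ndarray:
    """S = Sigma_u + W + sigma^2 * 11' (symmetric by construction)."""
    M = W.shape[0]
    S = sigma_u + W + sigma2 * np.ones((M, M))
    return 0.5 * (S + S.T)


def log_emission(d: np.ndarray, mu: float, S: np.ndarray) -> np.ndarray:
    """log N(d; mu*1, S) for one or many loci (rows of ``d``).

    Returns -inf for every locus when S is not positive definite: an
    invalid (e.g. negative-branch-length) regime is treated as a
    zero-probability emission rather than an error, so optimizers can
    propose and reject it smoothly.
    """
    d = np.atleast_2d(np.asarray(d, float))
    if np.any(np.isnan(d)):
        raise ValueError("invalid datum: NaN in transformed frequencies")
    M = S.shape[0]
    try:
        cf = cho_factor(S, lower=True)
    except np.linalg.LinAlgError:
        out = np.full(d.shape[0], -np.inf)
        return out if d.shape[0] > 1 else out
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    r = d - mu
    quad = np.einsum("lm,lm->l", r, cho_solve(cf, r.T).T)
    out = -0.5 * (M * _LOG2PI + logdet + quad)
    return out


class EmissionTable:
    """Precomputed S_{j,u}, factorizations and log-determinants.

    One entry per (hidden state j, sample-size cluster u).  States are
    given by their migration-rate vectors ``rates`` (n_states, I).
    """

    def __init__(self, graph: PopulationGraph, c: np.ndarray, rates: np.ndarray,
                 clusters: SampleSizeClusters, mu: float, sigma2: float) -> None:
        self.graph = graph
        self.c = np.asarray(c, float)
        self.rates = np.atleast_2d(np.asarray(rates, float))
        self.clusters = clusters
        self.mu = float(mu)
        self.sigma2 = float(sigma2)
        self.n_states = self.rates.shape[0]
        self._W = [drift_covariance(graph, self.c, r) for r in self.rates]
        self._entries: dict[tuple[int, int], tuple] = {}
        self._warned: set[int] = set()
        for j in range(self.n_states):
            for u in range(clusters.u):
                S = marginal_covariance(self._W[j], clusters.sigma(u), sigma2)
                try:
                    cf = cho_factor(S, lower=True)
                    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
                    self._entries[(j, u)] = (S, cf, logdet)
                except np.linalg.LinAlgError:
                    self._entries[(j, u)] = (S, None, None)

    def W(self, j: int) -> np.ndarray:
        return self._W[j]

    def S(self, j: int, u: int) -> np.ndarray:
        return self._entries[(j, u)][0]

    def is_valid(self, j: int, u: int) -> bool:
        return self._entries[(j, u)][1] is not None

    def solve(self, j: int, u: int, rhs: np.ndarray) -> np.ndarray:
        """S_{j,u}^{-1} rhs via the cached Cholesky factor."""
        cf = self._entries[(j, u)][1]
        if cf is None:
            raise np.linalg.LinAlgError("S not positive definite")
        return cho_solve(cf, rhs)

    def log_emissions(self, dataset: AlleleCountDataset) -> np.ndarray:
        """(L, n_states) log emission densities, vectorized per cluster."""
        L, M = dataset.L, dataset.M
        out = np.empty((L, self.n_states))
        assign = self.clusters.assignment
        for u in range(self.clusters.u):
            idx = np.where(assign == u)[0]
            if idx.size == 0:
                continue
            r = dataset.d[idx] - self.mu
            for j in range(self.n_states):
                S, cf, logdet = self._entries[(j, u)]
                if cf is None:
                    if not self._warned:
                        import warnings

                        warnings.warn(
                            "non-positive-definite emission covariance for at least "
                            "one state; such emissions are set to zero probability"
                        )
                        self._warned.add(j)
                    out[idx, j] = -np.inf
                else:
                    quad = np.einsum("lm,lm->l", r, cho_solve(cf, r.T).T)
                    out[idx, j] = -0.5 * (M * _LOG2PI + logdet + quad)
        return out
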