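"""Model-faithful simulator and detection-evaluation utility.

Generates allele counts exactly under the generative model: a root
frequency on the arcsine scale drawn from N(mu, sigma^2), Brownian drift
along the graph with locus-specific migration rates (covariance
W(c, w_l)), back-transform y = (sin(x) + 1)/2, and binomial sampling of
counts.  Migration-rate tracks come in three flavours: constant, the
peak-block benchmark design (background / intermediate / peak blocks),
or a Markov track drawn from the HMM prior itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .data import AlleleCountDataset
from .graph import PopulationGraph, drift_covariance
from .hmm import EdgeTransition, rate_matrix

__all__ = [
    "MigrationTrack",
    "SimulationTruth",
    "simulate_track",
    "simulate_dataset",
    "evaluate_detection",
    "four_population_graph",
]

#: benchmark block composition: background / intermediate / peak fractions
PEAK_DESIGN = (0.7, 0.2, 0.1)

_FOUR_POP_TIP = """
ROOT R
BRANCH R  A  0.03
BRANCH A  P1 0.06
BRANCH A  s2 0.03   # 2a: above the migration source
BRANCH s2 P2 0.05   # 2b: below the migration source
BRANCH R  C  0.03
BRANCH C  P3 0.06
BRANCH C  P4 0.07
MIG m1 s2 P3
LEAF P1 pop1
LEAF P2 pop2
LEAF P3 pop3
LEAF P4 pop4
"""

_FOUR_POP_INTERNAL = """
ROOT R
BRANCH R  A  0.03
BRANCH A  P1 0.06
BRANCH A  s2 0.03   # 2a
BRANCH s2 P2 0.05   # 2b
BRANCH R  C  0.03
BRANCH C  t3 0.03   # 3a: above the migration target
BRANCH t3 P3 0.04   # 3b: below the migration target
BRANCH C  P4 0.07
MIG m1 s2 t3
LEAF P1 pop1
LEAF P2 pop2
LEAF P3 pop3
LEAF P4 pop4
"""


def four_population_graph(target: str = "tip"):
    """Standard four-population demo graph with one migration edge.

    ``target="tip"``: the edge runs from a node ancestral to pop2 to the
    pop3 tip.  ``target="internal"``: the edge ends mid-way along the
    pop3 branch, splitting it into branches 3a/3b whose lengths are
    individually nonidentifiable under genome-constant migration.
    Returns a validated :class:`~locusmix.graph.PopulationGraph` with
    branch lengths set.
    """
    from .graph import parse_graph

    if target == "tip":
        return parse_graph(_FOUR_POP_TIP)
    if target == "internal":
        return parse_graph(_FOUR_POP_INTERNAL)
    raise ValueError("target must be 'tip' or 'internal'")


@dataclass
class MigrationTrack:
    """Per-locus true migration rates and block labels for one edge.

    ``labels``: 0 = background, 1 = intermediate, 2 = peak.
    """

    rates: np.ndarray
    labels: np.ndarray
    mode: str

    @property
    def L(self) -> int:
        return len(self.rates)


@dataclass
class SimulationTruth:
    """Everything drawn during a simulation, reproducible from the seed."""

    tracks: list[MigrationTrack]
    mu_l: np.ndarray     # per-locus root draws (arcsine scale)
    x: np.ndarray        # latent transformed population frequencies (L, M)
    y: np.ndarray        # latent population frequencies (L, M)
    c: np.ndarray
    mu: float
    sigma2: float
    seed: int


def simulate_track(L: int, mode: str, *, rate: float = 0.1,
                   background: float = 0.1, peak: float = 0.4,
                   intermediate: float | None = None, peak_width: int = 50,
                   kappa: float = 1.0, grid: np.ndarray | None = None,
                   variant: str = "ladder", phi: float = 0.5, zeta: float = 0.5,
                   attractor: int = 0, delta: float = 1.0,
                   seed: int | None = None) -> MigrationTrack:
    """Generate a migration-rate track of length ``L``.

    ``mode="constant"``: every locus at ``rate``.

    ``mode="peaks"``: the benchmark block design — 70% of blocks at the
    background rate, 10% at the peak rate and 20% intermediate, with
    each peak laid out as ``peak_width`` intermediate + ``peak_width``
    peak + ``peak_width`` intermediate blocks, peaks evenly spaced.
    ``intermediate`` defaults to the midpoint of background and peak.
    Raises ``ValueError("design mismatch")`` when the block arithmetic
    does not tile ``L`` exactly.

    ``mode="markov"``: sample the hidden chain exp(delta*kappa*Lambda)
    over ``grid`` from its stationary law (mirrors the HMM prior).
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if mode == "constant":
        return MigrationTrack(np.full(L, float(rate)), np.zeros(L, int), mode)
    if mode == "peaks":
        if intermediate is None:
            intermediate = 0.5 * (background + peak)
        n_peak = int(round(L * PEAK_DESIGN[2]))
        n_int = int(round(L * PEAK_DESIGN[1]))
        n_bg = L - n_peak - n_int
        if n_peak % peak_width != 0 or n_int != 2 * n_peak or n_bg != L - 3 * n_peak:
            raise ValueError("design mismatch: blocks do not tile the requested length")
        n_peaks = n_peak // peak_width
        rates = np.full(L, float(background))
        labels = np.zeros(L, int)
        peak_span = 3 * peak_width
        gap = (L - n_peaks * peak_span) // n_peaks
        extra = (L - n_peaks * peak_span) % n_peaks
        posn = gap // 2
        for p in range(n_peaks):
            sl_i1 = slice(posn, posn + peak_width)
            sl_pk = slice(posn + peak_width, posn + 2 * peak_width)
            sl_i2 = slice(posn + 2 * peak_width, posn + 3 * peak_width)
            rates[sl_i1] = intermediate
            rates[sl_pk] = peak
            rates[sl_i2] = intermediate
            labels[sl_i1] = 1
            labels[sl_pk] = 2
            labels[sl_i2] = 1
            posn += peak_span + gap + (1 if p < extra else 0)
        if int((labels == 2).sum()) != n_peak:
            raise ValueError("design mismatch: peak layout overflow")
        return MigrationTrack(rates, labels, mode)
    if mode == "markov":
        if grid is None:
            raise ValueError("markov mode requires a rate grid")
        grid = np.asarray(grid, float)
        J = len(grid)
        Lam = (rate_matrix(J, "ladder") if variant == "ladder"
               else rate_matrix(J, "attractor", phi, zeta, attractor))
        edge = EdgeTransition(Lam, kappa)
        rng = np.random.default_rng(seed)
        P = edge.P(delta)
        states = np.empty(L, int)
        states[0] = rng.choice(J, p=edge.pi)
        for l in range(1, L):
            states[l] = rng.choice(J, p=P[states[l - 1]])
        return MigrationTrack(grid[states], states, mode)
    raise ValueError(f"unknown track mode {mode!r}")


def simulate_dataset(graph: PopulationGraph, c: np.ndarray,
                     tracks: list[MigrationTrack] | MigrationTrack,
                     mu: float = -0.5, sigma2: float = 0.3,
                     N: int | np.ndarray = 100,
                     positions: np.ndarray | None = None,
                     chrom: str | np.ndarray = "1",
                     seed: int | None = None,
                     n_loci: int | None = None
                     ) -> tuple[AlleleCountDataset, SimulationTruth]:
    """Draw allele counts under the generative model.

    Per locus l: mu_l ~ N(mu, sigma2); x_l ~ N(mu_l*1, W(c, w_l)) with
    w_l the per-edge rates from the tracks; y = (sin(x)+1)/2; counts
    n ~ Binomial(N, y).  Positions default to 1 kb spacing (independent
    1,000-bp segments) on a single chromosome.
    """
    if isinstance(tracks, MigrationTrack):
        tracks = [tracks]
    if len(tracks) != graph.I:
        raise ValueError("invalid generative parameters: one track per migration edge required")
    if tracks:
        L = tracks[0].L
    elif n_loci is not None:
        L = int(n_loci)
    else:
        raise ValueError("invalid generative parameters: n_loci required without tracks")
    if any(t.L != L for t in tracks):
        raise ValueError("invalid generative parameters: track length mismatch")
    c = np.asarray(c, float)
    M = graph.M
    rng = np.random.default_rng(seed)
    W_rates = np.column_stack([t.rates for t in tracks]) if graph.I else np.zeros((L, 0))
    # cache the covariance factor per unique rate vector (tracks are blocky)
    uniq, inv = (np.unique(W_rates, axis=0, return_inverse=True)
                 if graph.I else (np.zeros((1, 0)), np.zeros(L, int)))
    chols = []
    for wv in uniq:
        W = drift_covariance(graph, c, wv)
        vals = np.linalg.eigvalsh(W)
        if vals[0] < -1e-10:
            raise ValueError("invalid generative parameters: drift covariance not PSD")
        chols.append(np.linalg.cholesky(W + 1e-12 * np.eye(M)))
    mu_l = mu + np.sqrt(sigma2) * rng.standard_normal(L) if sigma2 > 0 else np.full(L, mu)
    z = rng.standard_normal((L, M))
    x = np.empty((L, M))
    for k, Lc in enumerate(chols):
        idx = inv == k
        x[idx] = mu_l[idx, None] + z[idx] @ Lc.T
    y = 0.5 * (np.sin(x) + 1.0)
    Nmat = np.broadcast_to(np.asarray(N, int), (L, M)).copy()
    n = rng.binomial(Nmat, y)
    if positions is None:
        positions = 1000.0 * (np.arange(L) + 1)
    chrom_arr = np.broadcast_to(np.asarray(chrom, dtype=object), (L,)).copy()
    ds = AlleleCountDataset(n, Nmat, chrom_arr, positions, graph.populations)
    truth = SimulationTruth(tracks, mu_l, x, y, c, float(mu), float(sigma2),
                            seed if seed is not None else -1)
    return ds, truth


def evaluate_detection(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (midranks for ties) of scores against binary labels."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))
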