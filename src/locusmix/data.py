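"""Per-locus allele-count data and the arcsine-scale transform.

Observed derived counts ``n`` out of totals ``N`` give frequencies
``f = n/N``; the variance-stabilizing transform ``d = arcsin(2f - 1)``
maps [0, 1] onto [-pi/2, pi/2] and removes the f(1-f) factor from both
the drift and the binomial sampling variance, leaving a diagonal
sampling covariance diag(1/N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AlleleCountDataset", "transform_counts"]


def transform_counts(n: np.ndarray, N: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (d, f) with f = n/N and d = arcsin(2f - 1), elementwise.

    Raises ``ValueError`` on counts outside [0, N] or totals < 1 (loci
    with an unobserved population must be dropped before transforming).
    """
    n = np.asarray(n, float)
    N = np.asarray(N, float)
    if np.any(N < 1):
        raise ValueError("total allele count N < 1: locus must be rejected")
    if np.any(n < 0) or np.any(n > N):
        raise ValueError("derived count outside [0, N]")
    f = n / N
    d = np.arcsin(2.0 * f - 1.0)
    return d, f


@dataclass
class AlleleCountDataset:
    """Sorted per-locus, per-population allele counts with positions.

    Attributes
    ----------
    n, N : (L, M) integer arrays of derived and total allele counts.
    chrom : (L,) chromosome labels.
    pos : (L,) positions (bp, or cM if a genetic map was applied).
    populations : list of M population labels (column order of n, N).
    """

    n: np.ndarray
    N: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    populations: list[str]
    d: np.ndarray = field(init=False)
    f: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n)
        self.N = np.asarray(self.N)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, float)
        if self.n.shape != self.N.shape or self.n.ndim != 2:
            raise ValueError("n and N must be equal-shape (L, M) arrays")
        if self.n.shape[1] != len(self.populations):
            raise ValueError("population labels do not match count columns")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            self.n = self.n[order]
            self.N = self.N[order]
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
        self.d, self.f = transform_counts(self.n, self.N)

    @property
    def L(self) -> int:
        return self.n.shape[0]

    @property
    def M(self) -> int:
        return self.n.shape[1]

    def chromosome_starts(self) -> np.ndarray:
        """Indices where a new chromosome (independent HMM chain) begins."""
        starts = [0]
        for l in range(1, self.L):
            if self.chrom[l] != self.chrom[l - 1]:
                starts.append(l)
        return np.array(starts, int)

    def distances(self) -> np.ndarray:
        """Within-chromosome gaps delta_l between consecutive loci.

        Entry ``l`` is the distance from locus ``l-1`` to locus ``l``;
        entries at chromosome starts are NaN (no transition there).
        """
        delta = np.full(self.L, np.nan)
        gaps = np.diff(self.pos)
        same = self.chrom[1:] == self.chrom[:-1]
        delta[1:][same] = gaps[same]
        if np.any(delta[1:][same] <= 0):
            raise ValueError("non-positive inter-locus distance; positions must be strictly increasing")
        return delta

    def rescaled_distances(self) -> tuple[np.ndarray, float]:
        """Distances divided by their genome-wide mean (kappa absorbs scale).

        Returns (rescaled delta, the rescaling constant).
        """
        delta = self.distances()
        mean = float(np.nanmean(delta)) if np.any(np.isfinite(delta)) else 1.0
        return delta / mean, mean

    # -- filtering -------------------------------------------------------
    def drop_monomorphic(self) -> "AlleleCountDataset":
        """Drop loci fixed (f=0 or f=1) in every population: no drift information."""
        keep = ~(np.all(self.n == 0, axis=1) | np.all(self.n == self.N, axis=1))
        return self._subset(keep)

    def filter_maf(self, maf: float) -> "AlleleCountDataset":
        """Keep loci whose global allele frequency lies in [maf, 1 - maf]."""
        tot = self.n.sum(axis=1) / self.N.sum(axis=1)
        keep = (np.minimum(tot, 1 - tot) >= maf)
        return self._subset(keep)

    def thin(self, min_distance: float) -> "AlleleCountDataset":
        """Greedily keep loci at least ``min_distance`` apart within chromosomes."""
        keep = np.zeros(self.L, bool)
        last_chrom, last_pos = None, -np.inf
        for l in range(self.L):
            if self.chrom[l] != last_chrom or self.pos[l] - last_pos >= min_distance:
                keep[l] = True
                last_chrom, last_pos = self.chrom[l], self.pos[l]
        return self._subset(keep)

    def _subset(self, keep: np.ndarray) -> "AlleleCountDataset":
        return AlleleCountDataset(
            self.n[keep], self.N[keep], self.chrom[keep], self.pos[keep],
            list(self.populations),
        )

    # -- tables ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = {"chrom": self.chrom, "pos": self.pos.astype(int)}
        for m, p in enumerate(self.populations):
            cols[f"n_{p}"] = self.n[:, m]
            cols[f"N_{p}"] = self.N[:, m]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleCountDataset":
        pops = [c[2:] for c in df.columns if c.startswith("n_")]
        n = df[[f"n_{p}" for p in pops]].to_numpy()
        N = df[[f"N_{p}" for p in pops]].to_numpy()
        return cls(n, N, df["chrom"].to_numpy(), df["pos"].to_numpy(), pops)
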