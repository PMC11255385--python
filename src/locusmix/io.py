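"""Readers and writers: VCF / counts tables in, per-locus results out."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import AlleleCountDataset
from .fitting import FittedModel
from .graph import Branch, MigrationEdge, PopulationGraph, parse_graph
from .hmm import MigrationGrid, PosteriorSummary

__all__ = [
    "PopulationMap",
    "read_population_map",
    "read_vcf_counts",
    "read_counts_table",
    "write_counts_table",
    "write_vcf",
    "write_results",
    "write_parameters",
    "read_parameters",
    "graph_to_text",
]


@dataclass
class PopulationMap:
    """Sample identifier -> population label."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty population map")

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.mapping.values()))


def read_population_map(path: str | Path) -> PopulationMap:
    """Two whitespace-separated columns: sample, population."""
    mapping = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        sample, pop = line.split()[:2]
        mapping[sample] = pop
    return PopulationMap(mapping)


# ---------------------------------------------------------------------------
# VCF

def read_vcf_counts(path: str | Path, popmap: PopulationMap, *,
                    maf: float = 0.0, biallelic_only: bool = True,
                    ignore_extra: bool = False,
                    genetic_map: pd.DataFrame | None = None
                    ) -> tuple[AlleleCountDataset, dict[str, int]]:
    """Aggregate VCF genotypes into per-population ALT/total allele counts.

    Per population: ``n`` = ALT alleles among called genotypes, ``N`` =
    called alleles.  Loci are dropped when not biallelic SNPs (if
    ``biallelic_only``), when the global ALT frequency has minor allele
    frequency below ``maf``, or when any population has N = 0.  Returns
    the dataset and a dict of drop counts by reason.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in popmap.mapping]
    if unmapped and not ignore_extra:
        raise ValueError(f"unmapped sample(s) in VCF: {unmapped[:5]}")
    pops = popmap.populations
    cols = {p: np.array([i for i, s in enumerate(samples)
                         if popmap.mapping.get(s) == p], int)
            for p in pops}
    if any(len(v) == 0 for v in cols.values()):
        raise ValueError("population map covers no retained VCF sample for some population")
    rows_n, rows_N, chroms, poss = [], [], [], []
    dropped = {"not_biallelic": 0, "maf": 0, "missing_population": 0}
    for var in vcf:
        if biallelic_only and (len(var.ALT) != 1 or not var.is_snp):
            dropped["not_biallelic"] += 1
            continue
        gt = np.asarray(var.genotype.array())[:, :-1]  # drop phasing column
        called = gt >= 0
        n = np.array([(gt[cols[p]] > 0).sum() for p in pops], int)
        N = np.array([called[cols[p]].sum() for p in pops], int)
        if np.any(N == 0):
            dropped["missing_population"] += 1
            continue
        f_global = n.sum() / N.sum()
        if min(f_global, 1 - f_global) < maf:
            dropped["maf"] += 1
            continue
        rows_n.append(n)
        rows_N.append(N)
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not rows_n:
        raise ValueError("no loci retained from VCF")
    pos = np.array(poss, float)
    chrom = np.array(chroms, object)
    if genetic_map is not None:
        pos = _interpolate_genetic_map(chrom, pos, genetic_map)
    ds = AlleleCountDataset(np.array(rows_n), np.array(rows_N), chrom, pos, pops)
    return ds, dropped


def _interpolate_genetic_map(chrom, pos, gmap: pd.DataFrame) -> np.ndarray:
    """Linear interpolation position(bp) -> cM per chromosome.

    ``gmap`` columns: chrom, pos, cM.
    """
    out = np.empty(len(pos))
    for ch in np.unique(chrom):
        sub = gmap[gmap["chrom"].astype(str) == str(ch)].sort_values("pos")
        if sub.empty:
            raise ValueError(f"genetic map has no entries for chromosome {ch}")
        sel = chrom == ch
        out[sel] = np.interp(pos[sel], sub["pos"].to_numpy(float),
                             sub["cM"].to_numpy(float))
    return out


def write_vcf(dataset: AlleleCountDataset, path: str | Path) -> None:
    """Write counts as diploid pseudo-genotypes (plain-text VCF 4.2).

    Each population contributes N/2 diploid samples; ALT alleles fill
    genotypes greedily (1/1 first, then 0/1).  Requires even totals.
    """
    if np.any(dataset.N % 2 != 0):
        raise ValueError("VCF export needs even allele totals (diploid samples)")
    n_samples = dataset.N.max(axis=0) // 2
    names = [f"{p}_{k}" for p, ns in zip(dataset.populations, n_samples)
             for k in range(ns)]
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    for ch in dict.fromkeys(dataset.chrom):
        lines.append(f"##contig=<ID={ch}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names))
    for l in range(dataset.L):
        gts = []
        for m, ns in enumerate(n_samples):
            total = int(dataset.N[l, m]) // 2
            alt = int(dataset.n[l, m])
            col = []
            for s in range(ns):
                if s >= total:
                    col.append("./.")
                elif alt >= 2:
                    col.append("1/1")
                    alt -= 2
                elif alt == 1:
                    col.append("0/1")
                    alt -= 1
                else:
                    col.append("0/0")
            gts.extend(col)
        lines.append(f"{dataset.chrom[l]}\t{int(dataset.pos[l])}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# counts tables

def read_counts_table(path: str | Path) -> AlleleCountDataset:
    """TSV with columns chrom, pos, then n_<pop>, N_<pop> per population."""
    return AlleleCountDataset.from_frame(pd.read_csv(path, sep="\t"))


def write_counts_table(dataset: AlleleCountDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# results

def graph_to_text(graph: PopulationGraph) -> str:
    lines = [f"ROOT {graph.root}"]
    for b in graph.branches:
        if b.length is None:
            lines.append(f"BRANCH {b.parent} {b.child}")
        else:
            lines.append(f"BRANCH {b.parent} {b.child} {b.length!r}")
    for e in graph.migration_edges:
        lines.append(f"MIG {e.id} {e.source} {e.target}")
    for node, pop in graph.leaves.items():
        lines.append(f"LEAF {node} {pop}")
    return "\n".join(lines) + "\n"


def write_results(model: FittedModel, summary: PosteriorSummary,
                  dataset: AlleleCountDataset, prefix: str | Path,
                  log_lines: list[str] | None = None) -> dict[str, Path]:
    """Per-locus TSV, parameter JSON and run log under ``prefix``.

    The per-locus table carries, per migration edge, the posterior mean
    rate and the excess/dearth FDR scores, plus the MAP state.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cols = {"chrom": dataset.chrom, "pos": dataset.pos.astype(int)}
    edge_ids = [e.id for e in model.graph.migration_edges] or ["none"]
    for i in range(summary.mean_rate.shape[1]):
        eid = edge_ids[i] if i < len(edge_ids) else f"edge{i}"
        cols[f"w_mean_{eid}"] = summary.mean_rate[:, i]
        cols[f"q_excess_{eid}"] = summary.q_excess[:, i]
        cols[f"q_dearth_{eid}"] = summary.q_dearth[:, i]
    cols["map_state"] = summary.map_state
    locus_path = prefix.with_suffix(".loci.tsv")
    pd.DataFrame(cols).to_csv(locus_path, sep="\t", index=False, float_format="%.6g")
    param_path = prefix.with_suffix(".params.json")
    write_parameters(model, param_path)
    log_path = prefix.with_suffix(".log")
    log_path.write_text("\n".join(log_lines or ["fit completed"]) + "\n")
    return {"loci": locus_path, "params": param_path, "log": log_path}


def write_parameters(model: FittedModel, path: str | Path) -> None:
    payload = {
        "graph": graph_to_text(model.graph),
        "branch_lengths": model.c.tolist(),
        "mu": model.mu,
        "sigma2": model.sigma2,
        "variant": model.variant,
        "kappa": model.kappa.tolist(),
        "phi": None if model.phi is None else model.phi.tolist(),
        "zeta": None if model.zeta is None else model.zeta.tolist(),
        "attractor": None if model.attractor is None else model.attractor.tolist(),
        "grid": [g.tolist() for g in model.grid.grids],
        "loglik": model.loglik,
        "n_iter": model.n_iter,
        "converged": model.converged,
        "negative_branch_lengths": model.negative_branch_lengths,
        "distance_rescale": model.distance_rescale,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_parameters(path: str | Path) -> FittedModel:
    p = json.loads(Path(path).read_text())
    graph = parse_graph(p["graph"])
    return FittedModel(
        graph=graph, c=np.array(p["branch_lengths"]), mu=p["mu"],
        sigma2=p["sigma2"], variant=p["variant"], kappa=np.array(p["kappa"]),
        phi=None if p["phi"] is None else np.array(p["phi"]),
        zeta=None if p["zeta"] is None else np.array(p["zeta"]),
        attractor=None if p["attractor"] is None else np.array(p["attractor"], int),
        grid=MigrationGrid([np.array(g) for g in p["grid"]]),
        loglik=p["loglik"], n_iter=p["n_iter"], converged=p["converged"],
        negative_branch_lengths=p["negative_branch_lengths"],
        distance_rescale=p["distance_rescale"],
    )
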