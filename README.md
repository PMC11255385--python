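# locusmix

Locus-specific mixture proportions on admixture graphs, inferred from
linked genome-wide allele frequencies.

## The problem

Admixture-graph methods in the TreeMix tradition model allele-frequency
change along a population graph as Gaussian drift and estimate a single
migration (mixture) proportion per edge for the whole genome.  When
selection acts on introgressed material, the effective rate of gene
flow varies along the genome — adaptive introgression pushes it up
locally, barriers push it down — and a genome-wide rate hides exactly
the loci one cares about.  `locusmix` keeps the graph fixed (topology
from prior work, e.g. TreeMix) and infers a **per-locus** mixture
proportion for every migration edge, using a hidden Markov model so
that neighbouring loci share information through linkage.  It is aimed
at population geneticists with allele counts from a handful of
populations (a VCF plus a sample→population map) and a working
admixture graph.

## The model

For locus *l* with per-population derived counts *n* out of *N*, the
observed frequencies *f = n/N* are arcsine-transformed,
*d = arcsin(2f − 1)*, which removes the *f(1−f)* factor from both drift
and sampling variance.  Given migration rates *w* on the graph's edges,
the transformed frequencies are modelled as

    d_l | z_l ~ N( μ·1 , Σ_l + W(c, w_{z_l}) + σ²·11′ )

where Σ_l = diag(1/N_l) is sampling noise, σ² is the variance of the
(integrated-out) transformed root frequency around its mean μ, and
W(c, w) = Σ_k c_k J_k is the drift covariance: each branch *k* of
length c_k contributes the outer product of its leaf-inclusion
probabilities p_mk, obtained by opening each migration edge *i*
independently with probability w_i (a mixture over the 2^I open/closed
edge configurations).

The hidden state z_l picks each edge's rate from a discrete grid
(default 21 rates on [0, 1]) and evolves along the genome as a
continuous-time Markov chain integrated over inter-locus distance:
P_l = exp(δ_l κ Λ).  Two generators are supported — a symmetric
*ladder* (nearest-neighbour moves) and an *attractor* ladder with a
distinguished background state the chain reverts to (toward at rate
1+ζ, away at 1−ζ, leaving the attractor at rate φ, with φ, ζ ∈ (0, 1]).
Parameters (branch lengths, root prior, transition parameters) are
learned by an empirical-Bayes recipe: sample covariance → Gaussian
mixture refinement → coercion onto the graph by weighted least
squares / Nelder–Mead → Baum–Welch with SQUAREM acceleration → search
over candidate attractor states.  Outputs per locus are the posterior
mean rate w̄_il and false-discovery-rate style scores for excess and
dearth of introgression, q_e(l) = 1 − P(z_l > a) and
q_d(l) = 1 − P(z_l < a).

## Worked example

`examples/03_simulate_and_scan.py` simulates 1,500 loci for four
populations with one migration edge (background rate 0.1 with peaks at
0.4) and refits them:

```
simulated 1500 loci x 4 populations (N=100 alleles each; background rate 0.1, peaks at 0.4)
fitted transition model: attractor (attractor at grid index 1)
log-likelihood: -3119.3
posterior-mean rate MAE vs truth: 0.060
AUC, peak vs background loci:     0.999
```

The fitted attractor sits at grid index 1 — the simulated background
rate 0.1 on the 11-point grid — the per-locus posterior mean deviates
from the simulated track by 0.06 on average, and elevated-migration
regions rank almost perfectly above background (AUC 0.999).  The other
examples cover the drift covariance (`01`), the transition models
(`02`) and the VCF workflow (`04`).

## Command line

```sh
locusmix simulate --graph graph.txt --track peaks --L 10000 --out sim
locusmix fit --counts sim.counts.tsv --graph graph.txt --out run
locusmix fit --vcf cohort.vcf --popmap popmap.txt --graph graph.txt \
             --maf 0.05 --out run
locusmix posteriors --params run.params.json --counts sim.counts.tsv --out run2
```

Graph files are plain text (`ROOT`, `BRANCH parent child [length]`,
`MIG id source target`, `LEAF node population`); see
`docs/methods.md` for conventions (pre-split branches at migration
attachment points; opposed edge pairs are auto-oriented).

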