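# Methods

This note documents the model as implemented, the defaults and why they
were chosen, the numerics, and what the simulator does and does not
emulate.

## Model

### Drift covariance on the graph

A population graph is a rooted tree of drift branches (lengths `c_k`,
dimensionless drift units) plus directed migration edges carrying no
length.  A binary configuration `b` opens or closes every migration
edge; an open edge re-parents its *target node* to the migration
source, bypassing the target's incoming tree branch.  Opening edge `i`
independently with probability `w_i` gives each leaf `m` a marginal
probability `p_mk` that branch `k` lies on its root path, and the drift
covariance of the arcsine-transformed frequencies is
`W = Σ_k c_k p_k p_k'`.  Two equivalent computations are implemented:
exhaustive enumeration of the `2^I` configurations (capped at `I ≤ 12`,
overridable) and an exact per-leaf mixture recursion (each edge bit is
encountered at most once on a root path, so linearity of expectation
applies); tests require them to agree to 1e−12.

Configuration semantics follow the mixture reading: a bit selects the
effective parent of the edge's target, so leaves that can never reach a
branch are unaffected by that edge's rate, and donor-side branches
enter a recipient's variance with weight `w²`.

Bidirectional migration between two branches is modelled as two opposed
edges ordered by one inserted zero-length branch (the source of one
edge becomes, via the new branch, the ancestor of the opposite edge's
target), which makes every configuration acyclic.  The parser applies
this rewrite automatically; three or more mutually opposed edges on one
branch pair are rejected.

Negative branch lengths are accepted by the covariance code and flagged
on the fitted model — they are a useful diagnostic of an
over-parameterized graph — while the emission code guards positive
definiteness (below).

### Emissions

`d_l ~ N(μ·1, S)` with `S = Σ_u + W(c, w_j) + σ²·11′`.  Sampling
matrices are reduced to at most `u` representatives (default 10) by
iteratively merging the two least-frequent sample-size vectors into
their occurrence-weighted average; ties are broken by merging the
lexicographically smallest pair so the reduction is deterministic.
With finitely many states and clusters, every `S_{j,u}` and its
Cholesky factor is computed once per Baum–Welch iteration.

A non-positive-definite `S` (possible when branch lengths go negative)
is treated as a zero-probability emission (−∞ log-density, one warning
per table), not an exception, so optimizers can propose and smoothly
reject such regimes.  Loci monomorphic in **all** populations carry no
information and sit on the boundary of the normal approximation; they
are dropped by default (`keep_monomorphic` to retain).  Polarization of
the counted allele only flips the sign of `d` and `μ`; either
polarization is accepted and `μ`'s sign is reported as-is.

### Hidden chain

Per edge, rates live on a grid (default `J = 21` equally spaced values
on [0, 1]; equal spacing is a readability choice — posterior means then
interpolate naturally).  The chain is a continuous-time ladder:
`P = exp(δ κ Λ)` with the generator either symmetric or carrying an
attractor state `a` (toward-rate `1+ζ`, away-rate `1−ζ`, attractor row
`(φ, −2φ, φ)`, boundary rows at unit rate; an attractor at a boundary
gets row `(−φ, φ)`).  `φ, ζ ∈ (0, 1]` keeps the attractor the
stationary mode; the orientation "1+ζ toward the attractor" is the one
that yields that property and is verified by tests on a φ×ζ grid.
Tridiagonal generators are reversible, so each is symmetrized by its
stationary square root and diagonalized once (`eigh`); each distinct
distance then costs one congruence.  Chains with a zero off-diagonal
rate (ζ = 1) fall back to `scipy.linalg.expm`.  Joint transitions over
several edges factorize (Kronecker product), and a factorized
matrix-vector application is available for large products.

Inter-locus distances (bp, or cM via an optional genetic map) are
rescaled by their genome-wide mean so κ is O(1) for the optimizer; the
rescaling constant is stored in the output metadata.  Chromosomes are
independent chains; each starts from the stationary law of the fitted
generator (parameter-free and consistent with long-run behaviour —
the alternative, a uniform start, differs only at the first locus per
chromosome).  The forward–backward pass is scaled (per-locus
normalization) rather than log-space: with per-locus scaling constants
the two are numerically equivalent and the scaled form vectorizes the
expected-transition accumulation, which is gathered per distinct
distance value.

### Posterior summaries

Per locus and edge: posterior mean rate `w̄ = Σ_j w_j γ(j)` on the
edge's marginal chain, MAP state, and the background-relative scores
`q_e = P(z ≤ a)` and `q_d = P(z ≥ a)` (small `q_e`: confident excess;
`q_e + q_d − 1` equals the posterior mass at the attractor).  For
ladder fits, which have no attractor, the state of highest stationary
probability serves as a surrogate (ties — the ladder's stationary law
is uniform — broken by highest mean posterior across loci), and the
summary is flagged as using a surrogate.

## Fitting

1. **Init covariance** — sample covariance of `d`; ridge with a warning
   if rank-deficient.
2. **Mixture refinement** — `d_l ~ Σ_r π_r N(μ·1, C_r)` with free SPD
   component covariances and a shared mean.  ECM updates (μ by
   generalized least squares, `C_r` by responsibility-weighted scatter)
   keep the likelihood exactly monotone.  `σ²·11′` is not separately
   identifiable from a free `C_r`, so σ² is held at a moment estimate —
   the *minimum* off-diagonal sample covariance (population pairs on
   opposite sides of the root share essentially no drift, so that entry
   is σ² with the least drift contamination), floored at 1e−3 — and
   each `W_r` is reported as the PSD projection of
   `C_r − Σ̄ − σ²·11′` with `Σ̄` the occurrence-weighted mean sampling
   matrix.  Collapsed components trigger a reseeded restart (cap 5).
3. **Coercion** — minimize `Σ_r π_r ‖W_r − W(c, w_r)‖²_F` with weights
   `π_r` (components count by their data share).  `W` is linear in `c`
   for fixed rates, so `c` is profiled out by ridge-regularized least
   squares (the tiny ridge picks the balanced split for branch pairs
   that enter only through their sum, instead of an arbitrary huge
   one); Nelder–Mead runs only over the logit-rates, restarted `C`
   times (default 1,000) from uniform random rates.
4. **Choosing R** — increase R while every `π_r` exceeds 0.2 and the
   weighted RSS keeps decreasing; return the last accepted mixture.
5. **Ladder Baum–Welch** — E-step with the precomputed emission table;
   M-steps: μ analytic (GLS over all states/clusters), σ² by
   safeguarded Newton on log σ² (analytic first derivative, finite-
   difference second, step halving, bounded scalar search as fallback),
   branch lengths by safeguarded Newton with the analytic gradient
   (rank-one `∂S/∂c_k = p_k p_k'`), finite-difference Hessian,
   Levenberg damping and a step cap (near-flat directions — e.g. a
   split whose parts enter only through their sum — would otherwise
   launch unbounded steps at unchanged Q), and strict-improvement
   acceptance; κ by a bounded line search on log κ with bracket
   expansion.  Each M-step is a partial conditional maximization (GEM),
   which preserves monotonicity.  SQUAREM squared extrapolation runs on
   the packed parameter vector (c, μ, log σ², log κ, logit φ/ζ); an
   extrapolation that does not beat the plain double-EM step is
   discarded.  A plain EM step that *lowers* the likelihood beyond
   tolerance aborts with a diagnostic, since it indicates an M-step
   bug.  Initial κ is the reciprocal mean rescaled distance (=1 by
   construction).  Convergence: relative Δ log-likelihood < 1e−6
   (default), at most 500 iterations.
6. **Attractor search** — the top T (default 5) states by mean
   posterior under the ladder fit are tried as attractors, each with a
   full warm-started Baum–Welch run (branch lengths re-optimized: the
   criterion is final likelihood, and carrying stale lengths would bias
   the comparison); the best model by likelihood — possibly the ladder —
   is returned.  Candidate likelihoods can be near-tied, so driver code
   that relies on the selection (acceptance runs) uses tol = 1e−7.

## Simulator

Exactly the generative model: `μ_l ~ N(μ, σ²)`,
`x_l ~ N(μ_l·1, W(c, w_l))`, `y = (sin x + 1)/2`, `n ~ Binomial(N, y)`.
Tracks: constant; the benchmark peak-block design (fractions fixed at
70% background / 20% intermediate / 10% peak — at the canonical 10,000
blocks that is 7,000/2,000/1,000 — with each peak laid out as m
intermediate + m peak + m intermediate blocks, peaks evenly spaced and
m ∈ {50, 100, 200, 500}); or a Markov track sampled from the HMM prior
itself.  Default rates: background 0.1 (the benchmark's background);
peak 0.4 (midpoint of the benchmark's 0.2–0.6 range); intermediate =
midpoint of background and peak (the design names the level without a
number).  Positions default to 1 kb spacing, emulating independent
1,000-bp segments.

What passing tests do **not** show about real data: the simulator
shares the inference model's Gaussian-drift assumptions, so simulation
tests validate the machinery, not robustness to coalescent noise,
linkage within loci, ascertainment, or wrong topologies.  One genuine
mismatch *is* present and quantified by the recovery runs: the
back-transform `y = (sin x + 1)/2` folds for `|x| > π/2` (≈5% of loci
at σ² = 0.3), which compresses observed covariances by roughly 15%
relative to the linearized theory and biases fitted branch lengths and
σ² downward by a similar relative amount — an inherent limitation of
the arcsine-Gaussian approximation at large root-prior variance, not an
optimizer artifact (EM started at the true parameters moves to the same
higher-likelihood optimum).  Posterior mean *rates* are much less
affected.

## Problem sizes used by tests and the acceptance script

Chosen to exercise every stage at single-CPU scale: covariance
Monte-Carlo at 10⁵ loci; path-enumeration oracles at L ≤ 5, ≤ 4 states,
100 instances; EM/SQUAREM laws on 10 seeded 120-locus toy fits; the
recovery scan at L = 5,000, J = 11, N = 100, coercion restarts 100,
R ≤ 3; the nonidentifiability experiment at L = 1,500, J = 7,
ladder-only, 60 iterations, 10 replicates per condition, with the
"variable" condition a Markov track (grid of 11 rates, κ = 0.02) —
at reduced L the peak-block design is nearly constant and would not
restore identifiability, while the Markov track varies over the whole
chromosome like the full-scale variable scenarios.  The recovery
criterion "branch lengths within 20%" is evaluated as the mean absolute
relative error across branches.

## Known limitations

- The normal approximation to binomial sampling is unquantified below
  ~10 haplotypes per population; no correction is applied.
- Folding bias at large σ² (above).
- At most one migration edge may share a target node; topology
  inference and automatic edge placement are out of scope.
- Runtime scales linearly in loci and distinct Σ clusters,
  quadratically in J, and exponentially in the number of migration
  edges (state space is the product of grids).
- FDR-style `q` scores are per-locus posterior statements relative to
  the fitted attractor; with a surrogate attractor (ladder fit) they
  should be read with care.
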