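# Methods

This note documents the model, the numerical choices, and the design
decisions behind `revgwas`, together with what the simulation study does and
does not demonstrate.

## Problem and model

For one binary variant *v* (dominant-coded SNP presence) and P binary
phenotypes, the package searches the space of (K,L)-CNF combined phenotypes
— exactly K clauses, each an OR of up to L distinct phenotypes, clauses
ANDed — for the combination most associated with *v*. Allowing repeated
clauses and singleton clauses means the space contains every (K′,L′)-CNF
with K′ ≤ K, L′ ≤ L; with distinct clauses of exactly L phenotypes the
count is C(C(P,L), K) (`cnf_count`). Association is measured on the 2×2
table of the combined phenotype *u* against *v*; every supported statistic
is a function of (n_u, n_v, n_uv, M) alone, which is what makes both the
subject collapse and the (S,T)-based optimisation exact.

The one-sided Fisher exact p-value is the upper hypergeometric tail
P(X ≥ n_uv), X ~ Hypergeom(M, n_u, n_v), testing over-representation of the
variant among combined-phenotype carriers. It is monotone decreasing in
n_uv at fixed margins (verified exhaustively in the test suite over all
attainable overlaps for hundreds of margins). The protective direction is
handled by negating the variant vector rather than by a second tail.

## Subject collapse

Subjects with identical phenotype rows are merged: unique rows of Y in
lexicographic order (first column most significant), a multiplicity vector,
and per-profile carrier counts of each variant. Any CNF evaluated on
profiles and weighted by multiplicities/carrier counts reproduces the raw
(n_u, n_v, n_uv) exactly, so optima are unchanged (asserted in tests by
solving both forms). The reduction is what makes biobank-scale M tractable:
the MILP size scales with the number of distinct profiles (≤ 2^P), not M.

## The MILP

Variables `U[j,k]` (phenotype j in clause k), `Pc[i,k]` (profile i satisfies
clause k), `Pi[i]` (profile i has the combined phenotype), and counts S, T.
Constraint families:

* **or**: `U[j,k] − Pc[i,k] ≤ 0` for each profile i holding phenotype j, and
  `Pc[i,k] − Σ_{j held} U[j,k] ≤ 0`;
* **and**: `Pi − Pc[i,k] ≤ 0` and `Σ_k Pc[i,k] − Pi ≤ K−1`;
* **count**: `S = Σ m_i·Pi`, `T = Σ carriers_i·Pi` (equalities), and clause
  sizes `Σ_j U[j,k] ≤ L`.

On uncollapsed input this is K(M+P)+M+2 core variables and K(2M+O+1)+M
inequalities plus the two equalities; the tests assert these closed forms.
Two additional families are deliberate extensions, tagged separately so the
printed-size audit stays clean:

* **nonempty** (`Σ_j U[j,k] ≥ 1`): an all-zero clause would be an OR over
  nothing and force the combined phenotype to a constant 0; requiring at
  least one literal loses no generality because a repeated clause already
  emulates fewer clauses.
* **symmetry** (`Σ_j 2^j U[j,k]` non-increasing in k): clauses are
  interchangeable, and ordering them prunes symmetric branch-and-bound
  subtrees. Every clause multiset admits such an ordering, so the feasible
  set of CNFs is unchanged. Skipped for P > 30 where the weights would lose
  integer precision.

Only `U` is declared integer. The or-constraints pin each `Pc[i,k]` to
exactly 0 or 1 once the `U` are integral (some held literal is selected
⇒ `Pc ≥ 1`; none ⇒ `Pc ≤ 0`), and the and-constraints then pin `Pi`, hence
S and T. Declaring them continuous is therefore exact and moves all
branching onto the KP clause-membership variables.

Linear objectives are optimised directly in integer arithmetic: agreement
as 2T − S (plus the constant M − n_v), Hamming distance as the same
maximisation (agreement + hamming = M), covariance as M·T − n_v·S (affine
order-equivalent to the statistic; `solution_stat_value` maps back).
Non-linear monotone statistics go through the threshold boundary below.

Solver backend: an abstract contract (variables, linear constraints,
objective, solve with time limit/seed/MIP gap) with one implementation over
`scipy.optimize.milp` (HiGHS). HiGHS is deterministic for a fixed model;
the seed argument is part of the contract for backends that use one.
Feasibility probes pass a large relative MIP gap so the solver returns its
first incumbent: a feasible answer only needs *some* CNF meeting the
threshold, and infeasibility proofs are unaffected by the gap.

## Threshold boundary

A bound fisher_p(S,T) ≤ p₀ is equivalent, for each S, to T ≥ g(S) where
g(S) is the smallest attainable T passing the threshold. g is computed for
all S at once from the log-pmf table of the hypergeometric family
(gammaln-based, accumulated tails via `logaddexp`, chunked over S to bound
memory); a scalar binary-search path covers other monotone statistics.
Thresholds are handled as natural-log p-values throughout, so p₀ far below
double-precision underflow is fine.

The curve is pruned to its leftmost point plus the maximum-S point of each
level (the step function is reconstructed exactly by those points on a
contiguous domain; contiguity and monotonicity are verified per instance
and would raise rather than silently misclassify). A minimum-link corridor
simplification then fits the fewest line segments such that each segment
lies within [g, g + w], w = 1 − δ, over *every integer S* of every level it
covers (level endpoints suffice since lines are linear). Windows grow
greedily with doubling plus bisection; window feasibility is a 2-variable
LP, and since adding a level only adds constraints, maximal windows give
the minimum segment count at level granularity (a DP oracle in the tests
confirms minimality). Each window's line is the corridor-feasible line of
minimum total height, keeping the surrogate snug.

The MILP enforces T ≥ ĝ(S) − (w + δ/2). For integer T this is exactly
T ≥ g(S): on-or-above points satisfy T ≥ g ≥ ĝ − w, while strictly-below
points sit a full unit under g, hence at least δ/2 below the relaxed cut —
the extra δ/2 is numerical headroom for LP vertices that touch the corridor
boundary exactly. δ (default 0.001) therefore only trades segment count
against that margin, never correctness. Convex boundaries are encoded as
one half-plane per segment plus the S-domain (k + 2 constraints, no new
variables); otherwise a binary selector z_s per segment with a localised
copy y_s of S (2k variables, 2k + 3 constraints) activates exactly one
segment, with the segment S-ranges as the tightest valid big-M values.
Infeasible-S regions are excluded by the domain rather than extra cuts; the
upper attainability bounds T ≤ min(S, n_v) are implied by the count
constraints in the full model.

## Per-variant optimisation

The optimum Fisher p-value is found without ever optimising a non-linear
objective:

1. Seed an incumbent by hill-climbing from the best single phenotype
   (single-literal add/remove/swap moves, scored exactly on collapsed data,
   neighbour batches evaluated vectorised).
2. Repeatedly solve a feasibility MILP demanding a p-value strictly below
   the incumbent's exact p. A feasible answer yields a CNF (re-verified by
   evaluation, post-processed, hill-climb refined) that strictly improves
   the incumbent; an infeasible answer is an exact optimality certificate.
3. If improvements arrive in small steps, a doubling phase on −log p
   leapfrogs ahead and reuses any infeasibility bound it finds.

Termination is by proof, not tolerance: the returned p is the exact optimum
whenever the status is `optimized`. Probe/solve failures surface as
`undetermined`, never as silent drops. The hill-climber is an accelerator
only — every incumbent it proposes is scored exactly, so it cannot bias the
result, only shorten the probe chain.

Triage (does *any* (K,L)-CNF reach p₀?) is the first probe of the same
loop; a hill-climbed certificate skips the solve entirely when it already
passes.

## Two-stage design and baseline

Subjects are split by a seeded uniform permutation, first ⌊M/2⌋ to
discovery (the odd subject goes to validation). CNFs are fitted on
discovery only; validation evaluates the fixed CNF and requires p ≤ p₀
there too. Multiple testing is Bonferroni over the line-up (p₀ = .05/N by
default; genome-wide 5×10⁻⁸ is the intended real-data setting). The CMH
test (1 df, no continuity correction — the canonical definition) of variant
vs combined phenotype, stratified by the discovery-best single phenotype,
is computed on the validation half; strata with a zero margin contribute
nothing, and a fully degenerate stratification returns NaN. The GWAS
baseline scans single phenotypes under the identical split and thresholds;
with K = L = 1 the CNF search provably coincides with it (tested).

## Simulation study

`generate_dataset` emulates the calibration design: P = 11 phenotypes with
per-dataset prevalences drawn once from U(0.01, 0.2) (a stand-in for
disease-code prevalences, which in real cohorts come with correlations and
comorbidity structure that independent Bernoulli draws do not have); a
planted CNF with K distinct clauses of L distinct phenotypes, redrawn (≤100
times) if its indicator is constant; a pseudo-SNP equal to the indicator
with round(ε·M) entries flipped uniformly without replacement (adversarial
noise); and n_snps − 1 decoys drawn i.i.d. Bernoulli at the pseudo-SNP's
empirical frequency, resampled into a ±20% frequency band. The full
factorial grid K,L ∈ {1,2,3} × M ∈ {2000, 20000, 200000} × ε ∈ {0,0.1,0.2}
has 81 settings; per-trial seeds derive from a master seed through
`SeedSequence([master, setting, trial, stream])`, so any single trial is
re-runnable in isolation. Simulation runs score the planted (positive)
direction only; variant negation remains available and on by default in the
general `two_stage`/CLI path.

Passing pilot runs show that the pipeline detects planted logical structure
and controls validated false positives under the stated noise model; they
do not show robustness to correlated phenotypes, population structure,
linkage between variants, or miscoded missingness — real-data features the
generator deliberately omits.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run a reduced pilot: M = 2000,
12-SNP line-ups, K = L = 2 across all three noise levels, two to three
trials per setting, checking the qualitative findings (CNF-search TPR at
least the baseline's; validated decoys near zero). The full 81-setting ×
10-trial design runs through the same `run_grid` code path
(`revgwas simulate --grid --trials 10`). Note that a 12-SNP line-up makes
the Bonferroni threshold .05/12 rather than .05/50, so discovery-stage
decoy pass rates are expectedly higher than in the full design, while the
validation stage still removes essentially all of them. Exact-equivalence
checks (MILP vs enumeration ≥200 instances; boundary vs direct test,
exhaustive integer grids, ≥100 instances) run at P ≤ 5, M ≤ 60.

## Known limitations

* Binary genotypes only (dominant coding); dosage would need 2×3-table
  statistics or a regression formulation.
* Quantitative traits must be binarised upstream.
* The χ² statistic is not monotone in n_uv and is therefore rejected as a
  threshold/boundary statistic (it remains available for reporting).
* The boundary machinery assumes the level curve is non-decreasing with a
  contiguous feasible S-range; both hold empirically for the Fisher tail
  and are asserted per instance, failing loudly otherwise.
* HiGHS is markedly slower than commercial solvers on these models; the
  backend contract accepts alternatives, and any backend passing the
  enumeration-oracle suite is acceptable.
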