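# revgwas

Reverse GWAS: given a genetic variant, which *logical combination* of binary
phenotypes is most associated with it?

A standard GWAS fixes one phenotype and scans variants. `revgwas` inverts the
question for multi-phenotype cohorts (biobanks with disease codes,
autoimmune-trait panels, and similar): for a fixed variant *v* it searches the
space of **(K,L)-CNF** combined phenotypes — AND-combinations of K clauses,
each an OR of up to L phenotypes, e.g. `(IBD | psoriasis) & (thyroid | T1D)`
— for the combination *c* maximising an association statistic *f*(*c*, *v*).
CNFs keep the result interpretable and portable across cohorts: unlike a
weighted phenotype score, `(A|B)&(C|D)` means the same thing everywhere.

## Method

Inputs are binary matrices `X ∈ {0,1}^{M×N}` (subjects × SNPs, dominant
coding) and `Y ∈ {0,1}^{M×P}` (subjects × phenotypes). All supported
statistics (agreement, Hamming distance, covariance, correlation, χ²,
odds ratio, Cohen's κ, one-sided Fisher exact p) depend on a pair of vectors
only through `(n_u, n_v, n_uv, M)` — the 2×2 contingency table. The search is
an exact integer linear program:

* binary variables `U[j,k]` select phenotype *j* into clause *k*; linked
  0/1 quantities encode each subject's clause and combined-phenotype status;
  integer counts `S = n_u` and `T = n_uv` carry everything the objective
  needs. The formulation has `K(M+P)+M+2` core variables and `K(2M+O+1)+M`
  inequality plus two equality constraints (`O` = ones in `Y`).
* subjects with identical phenotype profiles are **collapsed** into weighted
  pseudo-subjects first — lossless for every statistic above, and the problem
  size then scales with the number of distinct profiles (≤ 2^P), not M.
* a threshold on a non-linear but `n_uv`-monotone statistic (Fisher's exact
  one-sided p ≤ p₀) becomes a lower boundary `T ≥ g(S)`; the level curve *g*
  is computed from hypergeometric tails, pruned, simplified to a
  minimum-segment piecewise-linear surrogate inside a corridor of width
  `1 − δ` (δ = 0.001 by default), and emitted as a handful of linear
  constraints that admit *exactly* the integer pairs passing the threshold.
* the per-variant optimum p-value is found by probing progressively stricter
  thresholds (each probe a feasibility MILP) until an infeasible probe
  certifies the incumbent CNF optimal; p-values are always recomputed
  exactly from counts, in log space so biobank-scale significance does not
  underflow.

The full workflow splits subjects into discovery and validation halves, fits
CNFs on discovery only, re-evaluates them fixed on validation (both halves
must meet the Bonferroni threshold), and reports a Cochran–Mantel–Haenszel
p-value stratified on the best single phenotype, to flag combinations driven
by one component. A single-phenotype GWAS baseline under the identical
two-stage design is included, as is a simulation study that plants a noisy
CNF pseudo-SNP in a line-up of frequency-matched decoy SNPs.

## Worked example

Plant a noiseless (2,2)-CNF phenotype among 600 subjects, hide its indicator
as one of four SNPs, and ask for it back:

```python
from revgwas.simulate import SimulationSpec, generate_dataset
from revgwas.search import two_stage, results_to_frame

spec = SimulationSpec(K=2, L=2, M=600, eps=0.0, n_snps=4, seed=5)
ds = generate_dataset(spec)
print("planted CNF:", ds.truth.to_string(ds.Y.col_ids))   # (ph0|ph4)&(ph2|ph6)
print("pseudo-SNP:", ds.pseudo_snp_id)                    # snp0

res = two_stage(ds.X, ds.Y, K=2, L=2, p0=0.05 / 4, split_seed=3, negate=False)
frame = results_to_frame(res, ds.Y.col_ids)
print(frame[["snp_id", "cnf", "S", "T", "nv",
             "p_discovery", "p_validation", "status"]].to_string(index=False))
```

prints

```
snp_id                   cnf    S    T  nv  p_discovery  p_validation    status
  snp0   (ph0|ph4)&(ph2|ph6)   11   11  11 2.712614e-20  5.084196e-23 validated
  snp1                       <NA> <NA>  10          NaN           NaN    failed
  snp2 (ph3|ph10)&(ph9|ph10)   52    6  11 4.758338e-03  7.196348e-01 optimized
  snp3       (ph2)&(ph3|ph5)    7    3  14 2.554570e-03  1.000000e+00 optimized
```

The search recovers the planted combination exactly on the discovery half
(`S = T = nv = 11`: all 11 carriers of the combined phenotype carry the
variant), and it replicates on the validation half — status `validated`.
Two decoys clear the discovery threshold by chance (`optimized`) but
collapse on validation (p ≈ 0.72 and 1.0); one decoy is `failed`, meaning
no (2,2)-CNF reaches the threshold for it at all.

The same pipeline is available from the shell:

```
revgwas run --genotype geno.tsv --phenotype pheno.tsv -K 2 -L 2
revgwas baseline --genotype geno.tsv --phenotype pheno.tsv
revgwas simulate -K 2 -L 2 -M 2000 --eps 0.1 --trials 10 --seed 1
```

Inputs are TSVs with a header row of column ids and a first column of
subject ids; results are written as TSVs with one row per (variant,
orientation).

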