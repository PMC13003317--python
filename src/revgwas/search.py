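"""Variant-level orchestration: triage, p-value optimisation, the
discovery/validation two-stage design, and the single-phenotype GWAS
baseline.

The per-variant workflow mirrors how the method is meant to be used:

1. *Triage* — one feasibility MILP per variant (and per negated variant)
   asking whether *any* (K,L)-CNF reaches the significance threshold ``p0``.
2. *Optimisation* — for passing variants, find the most associated CNF by
   probing progressively stricter thresholds on ``-log p``: repeated
   demands for a p-value strictly below the incumbent's, with a doubling
   phase to leapfrog slow improvement chains, until an infeasible probe
   certifies the incumbent optimal.  Every probe is a feasibility MILP with
   the agreement objective (solved to feasibility, not proven optimality);
   the returned p-value is always recomputed exactly from the counts of the
   returned CNF.
3. *Validation* — the optimised CNF is evaluated, fixed, on the held-out
   half; nothing is re-fitted.

All p-value arithmetic is done on natural-log scale so that extreme
significance levels at large sample sizes do not underflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .assoc_stats import cmh_test, fisher_log_pvalue
from .io_model import (
    BinaryMatrix,
    CNFPhenotype,
    CollapsedData,
    check_aligned,
    collapse_subjects,
)
from .ilp_core import (
    build_formulation,
    evaluate_cnf,
    extract_cnf,
    postprocess_cnf,
    solve,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "triage",
    "optimize_variant",
    "two_stage",
    "gwas_baseline",
    "split_subjects",
    "results_to_frame",
]

#: iteration caps for the doubling / improvement phases
MAX_DOUBLINGS = 60
MAX_POLISH = 40


@dataclass(frozen=True)
class AssociationResult:
    """Outcome for one (variant, orientation) pair."""

    snp_id: str
    negated: bool
    cnf: CNFPhenotype | None
    S: int | None
    T: int | None
    nv: int | None
    log_p_discovery: float | None      # natural log
    log_p_validation: float | None = None
    cmh_p: float | None = None
    best_single: str | None = None
    status: str = "failed"             # failed | triage-pass | optimized |
    #                                    validated | undetermined

    @property
    def p_discovery(self) -> float | None:
        return None if self.log_p_discovery is None else math.exp(
            self.log_p_discovery)

    @property
    def p_validation(self) -> float | None:
        return None if self.log_p_validation is None else math.exp(
            self.log_p_validation)


def _variant_column(X: BinaryMatrix, snp_id: str, negated: bool) -> np.ndarray:
    col = X.column(snp_id)
    return (1 - col) if negated else col


def _carriers(collapsed: CollapsedData, snp_id: str,
              negated: bool) -> np.ndarray:
    j = collapsed.snp_ids.index(snp_id)
    c = collapsed.carrier_counts[:, j]
    return (collapsed.multiplicity - c) if negated else c


def _orientations(snp_ids, negate: bool):
    for sid in snp_ids:
        yield sid, False
        if negate:
            yield sid, True


def triage(
    X: BinaryMatrix,
    Y: BinaryMatrix,
    K: int,
    L: int,
    p0: float,
    negate: bool = True,
    backend=None,
    time_limit: float | None = None,
    collapsed: CollapsedData | None = None,
) -> tuple[list[tuple[str, bool]], dict[tuple[str, bool], str]]:
    """Feasibility pass over all variants.

    Returns the (snp_id, negated) pairs for which some (K,L)-CNF attains
    ``fisher_p <= p0``, plus a status map; a solver timeout marks the pair
    ``"undetermined"`` rather than dropping it.
    """
    check_aligned(X, Y)
    if collapsed is None:
        collapsed = collapse_subjects(X, Y)
    ln_p0 = math.log(p0)
    passing: list[tuple[str, bool]] = []
    status: dict[tuple[str, bool], str] = {}
    for sid, neg in _orientations(X.col_ids, negate):
        carriers = _carriers(collapsed, sid, neg)
        # a hill-climbed CNF already past the threshold is a feasibility
        # certificate; otherwise the MILP decides (its infeasibility proof
        # is exact regardless of the probe gap)
        scorer = _CNFScorer(collapsed, carriers)
        j0, _ = scorer.best_single()
        _, ln_best = scorer.refine(CNFPhenotype((frozenset([j0]),) * K), K, L)
        if ln_best <= ln_p0:
            passing.append((sid, neg))
            status[(sid, neg)] = "triage-pass"
            continue
        f = build_formulation(carriers, collapsed, K, L,
                              objective="feasibility",
                              threshold=ln_p0, threshold_is_log=True)
        sol = solve(f, backend=backend, time_limit=time_limit,
                    mip_rel_gap=PROBE_GAP)
        if sol.status == "optimal":
            passing.append((sid, neg))
            status[(sid, neg)] = "triage-pass"
        elif sol.status == "infeasible":
            status[(sid, neg)] = "failed"
        else:
            status[(sid, neg)] = "undetermined"
            logger.warning("triage undetermined for %s (negated=%s): %s",
                           sid, neg, sol.status)
    return passing, status


class _CNFScorer:
    """Exact scorer and hill-climbing refiner over collapsed data.

    Used to seed and tighten the incumbent between MILP probes; every CNF it
    returns is scored exactly (log Fisher p from the true counts), so it can
    never mislead the optimisation — it only shortens the probe chain.
    """

    def __init__(self, collapsed: CollapsedData, carriers: np.ndarray):
        self.profiles = collapsed.profiles.astype(bool)
        self.m = collapsed.multiplicity.astype(np.int64)
        self.carriers = np.asarray(carriers, dtype=np.int64)
        self.M = int(self.m.sum())
        self.nv = int(self.carriers.sum())
        self.P = self.profiles.shape[1]

    def counts(self, clauses: list[frozenset[int]]) -> tuple[int, int]:
        ind = np.ones(self.profiles.shape[0], dtype=bool)
        for c in clauses:
            ind &= self.profiles[:, sorted(c)].any(axis=1)
        return int(self.m[ind].sum()), int(self.carriers[ind].sum())

    def ln_p(self, clauses: list[frozenset[int]]) -> float:
        S, T = self.counts(clauses)
        return float(fisher_log_pvalue(S, self.nv, T, self.M))

    def _neighbours(self, clauses: list[frozenset[int]], L: int):
        for k, c in enumerate(clauses):
            others = clauses[:k] + clauses[k + 1:]
            for j in c:
                if len(c) > 1:
                    yield others[:k] + [c - {j}] + others[k:]
            for j2 in range(self.P):
                if j2 in c:
                    continue
                if len(c) < L:
                    yield others[:k] + [c | {j2}] + others[k:]
                for j in c:
                    yield others[:k] + [(c - {j}) | {j2}] + others[k:]

    def refine(self, cnf: CNFPhenotype, K: int, L: int,
               max_steps: int = 60) -> tuple[CNFPhenotype, float]:
        """Greedy hill-climb on the exact log p over single-literal moves."""
        clauses = list(cnf.clauses)
        while len(clauses) < K:          # pad with a duplicate clause
            clauses.append(clauses[0])
        best = self.ln_p(clauses)
        for _ in range(max_steps):
            improved = False
            cand_clauses, cand_S, cand_T = [], [], []
            for nb in self._neighbours(clauses, L):
                S, T = self.counts(nb)
                cand_clauses.append(nb)
                cand_S.append(S)
                cand_T.append(T)
            if not cand_clauses:
                break
            lnp = fisher_log_pvalue(np.array(cand_S), self.nv,
                                    np.array(cand_T), self.M)
            i = int(np.argmin(lnp))
            if lnp[i] < best - 1e-12:
                best = float(lnp[i])
                clauses = cand_clauses[i]
                improved = True
            if not improved:
                break
        return CNFPhenotype(tuple(clauses)).canonical(), best

    def best_single(self) -> tuple[int, float]:
        S = (self.profiles * self.m[:, None]).sum(axis=0)
        T = (self.profiles * self.carriers[:, None]).sum(axis=0)
        lnp = fisher_log_pvalue(S, self.nv, T, self.M)
        j = int(np.argmin(lnp))
        return j, float(lnp[j])


#: probes stop at the first incumbent within this relative MIP gap; only
#: feasibility matters, exactness comes from infeasibility proofs
PROBE_GAP = 10.0


def optimize_variant(
    x_col: np.ndarray,
    Y: BinaryMatrix,
    K: int,
    L: int,
    p0: float = 1.0,
    snp_id: str = "variant",
    negated: bool = False,
    backend=None,
    time_limit: float | None = None,
    collapsed: CollapsedData | None = None,
    carriers: np.ndarray | None = None,
) -> AssociationResult:
    """Find the CNF minimising the one-sided Fisher p-value for one variant.

    The incumbent starts at the hill-climbed best reachable from the top
    single phenotype.  The main loop then repeatedly asks the MILP for a CNF
    with a p-value strictly below the incumbent's (each answer is
    hill-climb-refined before becoming the new incumbent); an infeasible
    answer is an exact optimality certificate.  When the solver keeps
    returning small improvements, a doubling phase on ``-log p`` leapfrogs
    ahead to shorten the chain.  Every probe is a feasibility MILP; every
    reported p-value is recomputed exactly from the counts of an actual CNF,
    and termination is by infeasibility proof, not by a tolerance.
    """
    x_col = np.asarray(x_col)
    if collapsed is None or carriers is None:
        xm = BinaryMatrix(x_col.reshape(-1, 1), Y.row_ids, (snp_id or "v",),
                          kind="genotype")
        collapsed = collapse_subjects(xm, Y)
        carriers = collapsed.carrier_counts[:, 0]
    carriers = np.asarray(carriers)
    scorer = _CNFScorer(collapsed, carriers)
    M, nv = scorer.M, scorer.nv
    ln_p0 = math.log(p0) if p0 < 1 else 0.0

    incumbent: tuple[CNFPhenotype, float] | None = None

    def consider(cnf: CNFPhenotype, refine: bool = True):
        nonlocal incumbent
        if refine:
            cnf, ln_p = scorer.refine(cnf, K, L)
        else:
            ln_p = scorer.ln_p(list(cnf.clauses))
        if incumbent is None or ln_p < incumbent[1]:
            incumbent = (cnf, ln_p)

    j0, _ = scorer.best_single()
    consider(CNFPhenotype((frozenset([j0]),) * K))

    def probe(ln_thr: float) -> str:
        """Is any (K,L)-CNF with fisher_p <= exp(ln_thr) feasible?"""
        if incumbent is not None and incumbent[1] <= ln_thr:
            return "feasible"        # certificate in hand, no solve needed
        f = build_formulation(carriers, collapsed, K, L,
                              objective="feasibility",
                              threshold=ln_thr, threshold_is_log=True)
        sol = solve(f, backend=backend, time_limit=time_limit,
                    mip_rel_gap=PROBE_GAP)
        if sol.status != "optimal":
            return sol.status
        consider(postprocess_cnf(extract_cnf(sol, K, L, collapsed)))
        return "feasible"

    st = probe(ln_p0)
    if st == "infeasible":
        return AssociationResult(snp_id, negated, None, None, None, nv,
                                 None, status="failed")
    if st != "feasible":
        return AssociationResult(snp_id, negated, None, None, None, nv,
                                 None, status="undetermined")

    status = "undetermined"
    q_hi = None          # smallest -ln p proven unattainable, if any
    streak = 0
    for _ in range(MAX_POLISH):
        st = probe(incumbent[1] - 1e-9)
        if st == "infeasible":
            status = "optimized"     # incumbent certified optimal
            break
        if st != "feasible":
            break
        streak += 1
        if streak >= 3 and (q_hi is None or -incumbent[1] < q_hi):
            # slow improvement chain: leapfrog by doubling -ln p until the
            # solver says no (that bound is reused to cap later jumps)
            for _ in range(MAX_DOUBLINGS):
                q = max(2.0 * -incumbent[1], -incumbent[1] + math.log(2))
                if q_hi is not None and q >= q_hi:
                    break
                st = probe(-q)
                if st == "infeasible":
                    q_hi = q
                    break
                if st != "feasible":
                    break
            streak = 0
    else:
        logger.warning("optimisation did not converge for %s", snp_id)
    cnf, ln_p = incumbent
    S, T = scorer.counts(list(cnf.clauses))
    return AssociationResult(snp_id, negated, cnf, S, T, nv, ln_p,
                             status=status)


def split_subjects(M: int, split_seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random equal split: a seeded permutation, first floor(M/2) subjects
    to discovery, the rest (including the odd one out) to validation."""
    rng = np.random.default_rng(split_seed)
    perm = rng.permutation(M)
    half = M // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def _subset(mat: BinaryMatrix, rows: np.ndarray) -> BinaryMatrix:
    return BinaryMatrix(mat.values[rows],
                        tuple(np.asarray(mat.row_ids)[rows]),
                        mat.col_ids, kind=mat.kind)


def _best_single_phenotypes(X: BinaryMatrix, Y: BinaryMatrix,
                            negate: bool) -> dict[tuple[str, bool], tuple[str, float]]:
    """For each (variant, orientation): the single phenotype with the
    smallest one-sided Fisher p, and its natural-log p (vectorised scan)."""
    M = X.n_subjects
    nu = Y.values.sum(axis=0).astype(np.int64)       # per phenotype
    out: dict[tuple[str, bool], tuple[str, float]] = {}
    for sid, neg in _orientations(X.col_ids, negate):
        x = _variant_column(X, sid, neg).astype(np.int64)
        nv = int(x.sum())
        nuv = x @ Y.values.astype(np.int64)
        ln = fisher_log_pvalue(nu, nv, nuv, M)
        j = int(np.argmin(ln))
        out[(sid, neg)] = (Y.col_ids[j], float(ln[j]))
    return out


def two_stage(
    X: BinaryMatrix,
    Y: BinaryMatrix,
    K: int,
    L: int,
    p0: float,
    split_seed: int,
    negate: bool = True,
    backend=None,
    time_limit: float | None = None,
) -> list[AssociationResult]:
    """Discovery/validation run over every variant.

    CNFs are fitted on the discovery half only; validation evaluates the
    fixed CNF and requires ``p <= p0`` there as well.  The CMH p-value
    (association of variant and combined phenotype stratified by the
    discovery-best single phenotype) is computed on the validation half.
    """
    check_aligned(X, Y)
    if X.n_subjects < 2:
        raise ValueError("need at least two subjects to split")
    disc_rows, val_rows = split_subjects(X.n_subjects, split_seed)
    Xd, Yd = _subset(X, disc_rows), _subset(Y, disc_rows)
    Xv, Yv = _subset(X, val_rows), _subset(Y, val_rows)
    collapsed = collapse_subjects(Xd, Yd)
    ln_p0 = math.log(p0)
    best_single = _best_single_phenotypes(Xd, Yd, negate)

    results: list[AssociationResult] = []
    for sid, neg in _orientations(X.col_ids, negate):
        carriers = _carriers(collapsed, sid, neg)
        res = optimize_variant(
            _variant_column(Xd, sid, neg), Yd, K, L, p0=p0,
            snp_id=sid, negated=neg, backend=backend, time_limit=time_limit,
            collapsed=collapsed, carriers=carriers,
        )
        if res.status == "failed" or res.cnf is None:
            results.append(res)
            continue
        # fixed-CNF evaluation on the validation half
        ind_v = evaluate_cnf(res.cnf, Yv)
        x_v = _variant_column(Xv, sid, neg)
        S_v = int(ind_v.sum())
        nv_v = int(x_v.sum())
        T_v = int((ind_v & (x_v == 1)).sum())
        ln_p_val = float(fisher_log_pvalue(S_v, nv_v, T_v, Xv.n_subjects))
        bs_name, _ = best_single[(sid, neg)]
        _, cmh_p = cmh_test(x_v, ind_v, Yv.column(bs_name))
        validated = res.log_p_discovery <= ln_p0 and ln_p_val <= ln_p0
        results.append(replace(
            res,
            log_p_validation=ln_p_val,
            cmh_p=cmh_p,
            best_single=bs_name,
            status="validated" if validated else res.status,
        ))
    return results


def gwas_baseline(
    X: BinaryMatrix,
    Y: BinaryMatrix,
    p0: float,
    split_seed: int,
    negate: bool = True,
) -> list[AssociationResult]:
    """Standard single-phenotype GWAS under the same two-stage design.

    For each variant (and orientation) the best single phenotype on the
    discovery half is carried, unchanged, to the validation half.  With
    K = L = 1 the CNF search space degenerates to exactly this scan.
    """
    check_aligned(X, Y)
    disc_rows, val_rows = split_subjects(X.n_subjects, split_seed)
    Xd, Yd = _subset(X, disc_rows), _subset(Y, disc_rows)
    Xv, Yv = _subset(X, val_rows), _subset(Y, val_rows)
    ln_p0 = math.log(p0)
    best = _best_single_phenotypes(Xd, Yd, negate)
    results = []
    for (sid, neg), (pheno, ln_p_disc) in best.items():
        j = Y.col_ids.index(pheno)
        cnf = CNFPhenotype((frozenset([j]),))
        x_d = _variant_column(Xd, sid, neg)
        ind_d = Yd.column(pheno)
        if ln_p_disc > ln_p0:
            results.append(AssociationResult(
                sid, neg, cnf, int(ind_d.sum()),
                int((ind_d & (x_d == 1)).sum()), int(x_d.sum()),
                ln_p_disc, status="failed"))
            continue
        x_v = _variant_column(Xv, sid, neg)
        ind_v = Yv.column(pheno)
        ln_p_val = float(fisher_log_pvalue(
            int(ind_v.sum()), int(x_v.sum()),
            int((ind_v & (x_v == 1)).sum()), Xv.n_subjects))
        validated = ln_p_val <= ln_p0
        results.append(AssociationResult(
            sid, neg, cnf, int(ind_d.sum()),
            int((ind_d & (x_d == 1)).sum()), int(x_d.sum()),
            ln_p_disc, log_p_validation=ln_p_val, best_single=pheno,
            status="validated" if validated else "optimized"))
    return results


def results_to_frame(results: list[AssociationResult],
                     pheno_ids: tuple[str, ...] | None = None):
    """Tabulate results in the output TSV schema."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "snp_id": r.snp_id,
            "negated": int(r.negated),
            "cnf": "" if r.cnf is None else r.cnf.to_string(pheno_ids),
            "S": r.S, "T": r.T, "nv": r.nv,
            "p_discovery": r.p_discovery,
            "p_validation": r.p_validation,
            "log10_p_discovery": (None if r.log_p_discovery is None
                                  else r.log_p_discovery / math.log(10)),
            "log10_p_validation": (None if r.log_p_validation is None
                                   else r.log_p_validation / math.log(10)),
            "cmh_p": r.cmh_p,
            "best_single": r.best_single,
            "status": r.status,
        })
    frame = pd.DataFrame(rows)
    for col in ("S", "T", "nv"):
        frame[col] = frame[col].astype("Int64")
    return frame
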