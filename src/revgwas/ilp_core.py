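"""MILP formulation for the best CNF phenotype of one variant.

Decision variables (for K clauses over P phenotypes and U subject profiles):

* ``U[j,k]``   binary — phenotype j is used in clause k,
* ``Pc[i,k]``  0/1 — profile i satisfies clause k,
* ``Pi[i]``    0/1 — profile i has the combined phenotype,
* ``S``, ``T`` integer counts — combined-phenotype subjects, and those also
  carrying the variant (multiplicity-weighted on collapsed input).

Only the ``U`` variables carry an integrality requirement: the constraint
structure pins every ``Pc``, ``Pi`` and hence ``S`` and ``T`` to exact
integer values once the ``U`` are integral, so they are declared continuous
and branching happens on clause membership alone.

The OR constraints tie ``Pc`` to the clause memberships, the AND constraints
tie ``Pi`` to the clauses, and the count constraints define S and T with the
profile multiplicities / carrier counts as coefficients, so the formulation
is identical on raw or collapsed input.  Linear objectives (agreement,
Hamming distance, covariance) are affine in (S, T); non-linear monotone
statistics are handled as threshold constraints through the boundary
encoding, with agreement as the feasibility-mode objective.

The solver backend is a pluggable contract; the default wraps
``scipy.optimize.milp`` (HiGHS), which is deterministic for a fixed input.
An exhaustive enumeration oracle over all (K,L)-CNFs is provided for
verification on small instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, combinations_with_replacement

import numpy as np

from .assoc_stats import (
    STATS,
    ContingencySummary,
    StatSpec,
    compute_stat,
    fisher_log_pvalue,
)
from .boundary import (
    encode_lower_bound,
    prune_boundary,
    simplify_boundary,
    threshold_curve,
    DEFAULT_DELTA,
)
from .io_model import BinaryMatrix, CNFPhenotype, CollapsedData, ValidationError

__all__ = [
    "Formulation",
    "Solution",
    "ScipyHighsBackend",
    "evaluate_cnf",
    "build_formulation",
    "solve",
    "extract_cnf",
    "postprocess_cnf",
    "enumerate_cnf_oracle",
    "cnf_count",
]


class Formulation:
    """A mixed-integer linear program assembled by name.

    Constraints carry a family tag (``or``, ``and``, ``clause_size``,
    ``count_eq``, ``nonempty``, ``boundary``) so formulation sizes can be
    audited against the closed-form counts.
    """

    def __init__(self):
        self.var_names: list[str] = []
        self.var_index: dict[str, int] = {}
        self.var_bounds: list[tuple[float, float]] = []
        self.var_integer: list[bool] = []
        self.constraints: list[tuple[dict[str, float], float | None,
                                     float | None, str]] = []
        self.objective: dict[str, float] = {}
        self.sense: str = "max"
        self.meta: dict = {}

    def add_var(self, name: str, lb: float = 0.0, ub: float = 1.0,
                integer: bool = True) -> int:
        if name in self.var_index:
            raise ValueError(f"duplicate variable {name!r}")
        idx = len(self.var_names)
        self.var_index[name] = idx
        self.var_names.append(name)
        self.var_bounds.append((lb, ub))
        self.var_integer.append(integer)
        return idx

    def add_constraint(self, coeffs: dict[str, float], lb=None, ub=None,
                       family: str = "misc") -> None:
        for name in coeffs:
            if name not in self.var_index:
                raise ValueError(f"constraint references unknown variable {name!r}")
        self.constraints.append((dict(coeffs), lb, ub, family))

    def set_objective(self, coeffs: dict[str, float], sense: str = "max") -> None:
        self.objective = dict(coeffs)
        self.sense = sense

    @property
    def n_vars(self) -> int:
        return len(self.var_names)

    def constraint_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, _, _, family in self.constraints:
            out[family] = out.get(family, 0) + 1
        return out

    def n_inequalities(self, families=("or", "and", "clause_size")) -> int:
        counts = self.constraint_counts()
        return sum(counts.get(f, 0) for f in families)

    def to_lp_string(self) -> str:
        """Export in the standard LP file dialect (debugging aid)."""
        lines = ["Maximize" if self.sense == "max" else "Minimize"]
        obj = " + ".join(f"{v} {n}" for n, v in self.objective.items()) or "0"
        lines.append(f" obj: {obj}")
        lines.append("Subject To")
        for idx, (coeffs, lb, ub, family) in enumerate(self.constraints):
            expr = " + ".join(f"{v} {n}" for n, v in coeffs.items())
            if lb is not None and ub is not None and lb == ub:
                lines.append(f" c{idx}_{family}: {expr} = {lb}")
            else:
                if ub is not None:
                    lines.append(f" c{idx}_{family}: {expr} <= {ub}")
                if lb is not None:
                    lines.append(f" c{idx}_{family}_lo: {expr} >= {lb}")
        lines.append("Bounds")
        for name, (lb, ub) in zip(self.var_names, self.var_bounds):
            lines.append(f" {lb} <= {name} <= {ub}")
        lines.append("General")
        lines.append(" " + " ".join(
            n for n, isint in zip(self.var_names, self.var_integer) if isint))
        lines.append("End")
        return "\n".join(lines)


@dataclass(frozen=True)
class Solution:
    status: str                       # optimal | infeasible | timeout | error
    objective: float | None
    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def intval(self, name: str) -> int:
        return int(round(self.values[name]))


class ScipyHighsBackend:
    """Default solver backend: scipy.optimize.milp (HiGHS).

    HiGHS is deterministic for a fixed model; ``seed`` is accepted for the
    backend contract but has no effect here.
    """

    name = "scipy-highs"

    def solve(self, f: Formulation, time_limit: float | None = None,
              seed: int | None = None,
              mip_rel_gap: float | None = None) -> Solution:
        from scipy.optimize import LinearConstraint, milp
        from scipy.sparse import lil_matrix

        n = f.n_vars
        c = np.zeros(n)
        for name, v in f.objective.items():
            c[f.var_index[name]] = v
        if f.sense == "max":
            c = -c
        A = lil_matrix((len(f.constraints), n))
        lb = np.full(len(f.constraints), -np.inf)
        ub = np.full(len(f.constraints), np.inf)
        for r, (coeffs, clo, cup, _) in enumerate(f.constraints):
            for name, v in coeffs.items():
                A[r, f.var_index[name]] = v
            if clo is not None:
                lb[r] = clo
            if cup is not None:
                ub[r] = cup
        integrality = np.array([1 if b else 0 for b in f.var_integer])
        bounds = np.array(f.var_bounds, dtype=float)
        from scipy.optimize import Bounds

        options = {}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        if mip_rel_gap is not None:
            options["mip_rel_gap"] = float(mip_rel_gap)
        res = milp(
            c,
            constraints=LinearConstraint(A.tocsr(), lb, ub),
            integrality=integrality,
            bounds=Bounds(bounds[:, 0], bounds[:, 1]),
            options=options,
        )
        if res.status == 0:
            obj = float(res.fun) * (-1 if f.sense == "max" else 1)
            values = {name: float(res.x[i]) for i, name in enumerate(f.var_names)}
            return Solution("optimal", obj, values)
        if res.status == 2:
            return Solution("infeasible", None)
        if res.status == 1:
            values = {}
            obj = None
            if res.x is not None:
                values = {name: float(res.x[i])
                          for i, name in enumerate(f.var_names)}
                obj = float(res.fun) * (-1 if f.sense == "max" else 1)
            return Solution("timeout", obj, values)
        return Solution("error", None)


DEFAULT_BACKEND = ScipyHighsBackend()


def evaluate_cnf(c: CNFPhenotype, Y: BinaryMatrix | np.ndarray) -> np.ndarray:
    """Indicator vector of the combined phenotype: row i is 1 iff every
    clause contains some phenotype j with Y[i, j] = 1."""
    values = Y.values if isinstance(Y, BinaryMatrix) else np.asarray(Y)
    c.check_indices(values.shape[1])
    out = np.ones(values.shape[0], dtype=bool)
    for clause in c.clauses:
        out &= values[:, sorted(clause)].any(axis=1)
    return out.astype(np.int8)


def build_formulation(
    carriers: np.ndarray,
    collapsed: CollapsedData,
    K: int,
    L: int,
    objective: str | StatSpec = "agreement",
    threshold: float | None = None,
    threshold_is_log: bool = False,
    direction: str = "over",
    delta: float = DEFAULT_DELTA,
    require_nonempty_clauses: bool = True,
) -> Formulation:
    """Assemble the MILP for one variant.

    Parameters
    ----------
    carriers
        Per-profile carrier counts of the variant (length U).
    objective
        One of the linear statistics (``agreement``, ``hamming``,
        ``covariance``) or ``"feasibility"``; feasibility mode requires a
        ``threshold`` (a Fisher p-value bound enforced through the boundary
        encoding) and optimises agreement, which works well as a surrogate.
    """
    if K < 1 or L < 1:
        raise ValidationError("K and L must be at least 1")
    profiles = collapsed.profiles
    m = collapsed.multiplicity
    carriers = np.asarray(carriers, dtype=np.int64)
    U_n, P = profiles.shape
    if carriers.shape != (U_n,):
        raise ValidationError("carrier vector length does not match profiles")
    if ((carriers < 0) | (carriers > m)).any():
        raise ValidationError("carrier counts outside [0, multiplicity]")
    M = int(m.sum())
    nv = int(carriers.sum())

    if isinstance(objective, StatSpec):
        objective = objective.name
    if objective not in ("agreement", "hamming", "covariance", "feasibility"):
        raise ValidationError(
            f"objective {objective!r} is not linear in (S, T); use the search "
            "module's threshold-driven optimisation for non-linear statistics"
        )
    if objective == "feasibility" and threshold is None:
        raise ValidationError("feasibility mode needs a threshold")

    f = Formulation()
    for k in range(K):
        for j in range(P):
            f.add_var(f"U_{j}_{k}")
    # Pc and Pi are declared continuous: the or-constraints pin Pc[i,k] to
    # exactly 0 or 1 once the U are integral (Pc >= U_jk for a held
    # phenotype in the clause, Pc <= sum of held U_jk), and the
    # and-constraints then pin Pi the same way, so integrality is implied
    # and branching happens on U only.
    for k in range(K):
        for i in range(U_n):
            f.add_var(f"Pc_{i}_{k}", integer=False)
    for i in range(U_n):
        f.add_var(f"Pi_{i}", integer=False)
    f.add_var("S", 0, M, integer=False)
    f.add_var("T", 0, nv, integer=False)

    # or: Pc[i,k] = 1 iff clause k holds a phenotype the profile has
    for k in range(K):
        for i in range(U_n):
            have = np.flatnonzero(profiles[i])
            for j in have:
                f.add_constraint({f"U_{j}_{k}": 1.0, f"Pc_{i}_{k}": -1.0},
                                 ub=0.0, family="or")
            f.add_constraint(
                {f"Pc_{i}_{k}": 1.0, **{f"U_{j}_{k}": -1.0 for j in have}},
                ub=0.0, family="or")
    # and: Pi[i] = 1 iff every clause holds
    for k in range(K):
        for i in range(U_n):
            f.add_constraint({f"Pi_{i}": 1.0, f"Pc_{i}_{k}": -1.0},
                             ub=0.0, family="and")
    for i in range(U_n):
        f.add_constraint(
            {**{f"Pc_{i}_{k}": 1.0 for k in range(K)}, f"Pi_{i}": -1.0},
            ub=float(K - 1), family="and")
    # counts
    f.add_constraint({"S": 1.0, **{f"Pi_{i}": -float(m[i]) for i in range(U_n)}},
                     lb=0.0, ub=0.0, family="count_eq")
    f.add_constraint(
        {"T": 1.0, **{f"Pi_{i}": -float(carriers[i])
                      for i in range(U_n) if carriers[i]}},
        lb=0.0, ub=0.0, family="count_eq")
    for k in range(K):
        f.add_constraint({f"U_{j}_{k}": 1.0 for j in range(P)},
                         ub=float(L), family="clause_size")
    if require_nonempty_clauses:
        for k in range(K):
            f.add_constraint({f"U_{j}_{k}": 1.0 for j in range(P)},
                             lb=1.0, family="nonempty")
    # clauses are interchangeable; order them by their membership pattern to
    # cut symmetric branches (every clause multiset has such an ordering);
    # skipped for wide phenotype sets where the 2^j weights lose precision
    for k in range(K - 1) if P <= 30 else ():
        coeffs = {f"U_{j}_{k}": float(2**j) for j in range(P)}
        for j in range(P):
            coeffs[f"U_{j}_{k + 1}"] = -float(2**j)
        f.add_constraint(coeffs, lb=0.0, family="symmetry")

    if threshold is not None:
        curve = threshold_curve(nv, M, threshold, "fisher_p", direction,
                                log=threshold_is_log)
        R = prune_boundary(curve)
        if not R:
            # no attainable table passes: encode plain infeasibility
            f.add_constraint({"S": 0.0}, lb=1.0, family="boundary")
        else:
            bounds_ = simplify_boundary(R, delta, nv=nv, M=M)
            enc = encode_lower_bound(bounds_)
            for name, lb_, ub_, isint in enc.aux_vars:
                f.add_var(name, lb_, ub_, integer=isint)
            for coeffs, clo, cup in enc.constraints:
                f.add_constraint(coeffs, lb=clo, ub=cup, family="boundary")
            f.meta["boundary_segments"] = bounds_
            f.meta["boundary_convex"] = enc.convex

    if objective in ("agreement", "feasibility"):
        f.set_objective({"T": 2.0, "S": -1.0}, sense="max")
        f.meta["objective_stat"] = "agreement"
        f.meta["objective_affine"] = (1.0, float(M - nv))  # stat = a*obj + b
    elif objective == "hamming":
        f.set_objective({"T": 2.0, "S": -1.0}, sense="max")
        f.meta["objective_stat"] = "hamming"
        f.meta["objective_affine"] = (-1.0, float(nv))
    elif objective == "covariance":
        f.set_objective({"T": float(M), "S": -float(nv)}, sense="max")
        f.meta["objective_stat"] = "covariance"
        f.meta["objective_affine"] = (1.0 / M**2, 0.0)
    f.meta.update(K=K, L=L, M=M, nv=nv, P=P, U=U_n)
    return f


def solve(f: Formulation, backend=None, time_limit: float | None = None,
          seed: int | None = None, mip_rel_gap: float | None = None) -> Solution:
    """Solve a formulation through a backend (default: scipy/HiGHS).

    ``mip_rel_gap`` relaxes proof of optimality (never of feasibility or
    infeasibility); feasibility-probe callers use it since any incumbent
    meeting the threshold suffices there.
    """
    backend = backend or DEFAULT_BACKEND
    kwargs = {}
    if mip_rel_gap is not None:
        kwargs["mip_rel_gap"] = mip_rel_gap
    return backend.solve(f, time_limit=time_limit, seed=seed, **kwargs)


def solution_stat_value(f: Formulation, sol: Solution) -> float:
    """Map the solver's objective back to the statistic's own scale."""
    a, b = f.meta["objective_affine"]
    return a * sol.objective + b


def extract_cnf(sol: Solution, K: int, L: int,
                collapsed: CollapsedData | None = None) -> CNFPhenotype:
    """Read the clause memberships out of a solution and re-verify them.

    If ``collapsed`` is given, the CNF is re-evaluated on the profiles and
    must reproduce the solver's combined-phenotype indicators exactly; any
    mismatch (solver numerical noise) raises instead of passing through.
    """
    clauses = []
    for k in range(K):
        clause = frozenset(
            j for name, v in sol.values.items()
            if v > 0.5 and name.startswith("U_")
            and int(name.split("_")[2]) == k
            for j in [int(name.split("_")[1])]
        )
        if not clause:
            raise ValidationError(f"solution has an empty clause (k={k})")
        if len(clause) > L:
            raise ValidationError(f"clause {k} uses more than L={L} phenotypes")
        clauses.append(clause)
    cnf = CNFPhenotype(tuple(clauses))
    if collapsed is not None:
        indicator = evaluate_cnf(cnf, collapsed.profiles)
        for i in range(collapsed.n_profiles):
            if abs(sol.values[f"Pi_{i}"] - indicator[i]) > 1e-6:
                raise ValidationError(
                    f"solver assignment disagrees with CNF evaluation at "
                    f"profile {i}; refusing to trust the solution"
                )
    return cnf.canonical()


def postprocess_cnf(c: CNFPhenotype) -> CNFPhenotype:
    """Keep only the distinct set-minimal clauses.

    Duplicate indices inside a clause are already impossible (clauses are
    sets); duplicate clauses are merged and any clause that is a superset of
    another is dropped — it is implied by the subset clause.  The result
    evaluates identically on every profile.
    """
    unique = list(dict.fromkeys(c.clauses))
    kept = [
        cl for cl in unique
        if not any(other < cl for other in unique)
    ]
    return CNFPhenotype(tuple(kept)).canonical()


def cnf_count(P: int, K: int, L: int) -> int:
    """Number of (K,L)-CNFs with distinct clauses of exactly L distinct
    phenotypes each: C(C(P, L), K)."""
    return math.comb(math.comb(P, L), K)


def enumerate_cnf_oracle(
    x_col: np.ndarray,
    Y: BinaryMatrix | np.ndarray,
    K: int,
    L: int,
    spec: StatSpec | str = "agreement",
    direction: str = "over",
    max_combinations: int = 10**6,
):
    """Exhaustively score every CNF with <= K clauses of <= L phenotypes.

    Clause repetition is allowed, so the space covers all (K', L')-CNFs with
    K' <= K, L' <= L.  Returns ``(best_cnf, best_value, best_summary)`` where
    value is the statistic on its own scale (for ``fisher_p``, the natural
    log of the p-value, to survive extreme significance).  Intended as a
    verification oracle on small instances; refuses combinatorially large
    ones.
    """
    if isinstance(spec, str):
        spec = STATS[spec]
    values = Y.values if isinstance(Y, BinaryMatrix) else np.asarray(Y)
    x = np.asarray(x_col).astype(bool)
    M, P = values.shape
    nv = int(x.sum())
    clause_sets = [frozenset(cmb) for size in range(1, L + 1)
                   for cmb in combinations(range(P), size)]
    n_cnfs = math.comb(len(clause_sets) + K - 1, K)
    if n_cnfs > max_combinations:
        raise ValueError(
            f"{n_cnfs} CNF combinations exceed the enumeration guard "
            f"({max_combinations})"
        )
    indicators = [values[:, sorted(cl)].any(axis=1) for cl in clause_sets]
    best = None
    for combo in combinations_with_replacement(range(len(clause_sets)), K):
        ind = indicators[combo[0]].copy()
        for ci in combo[1:]:
            ind &= indicators[ci]
        nu = int(ind.sum())
        nuv = int((ind & x).sum())
        if spec.name == "fisher_p":
            val = float(fisher_log_pvalue(nu, nv, nuv, M, direction))
        else:
            val = compute_stat(spec, ContingencySummary(nu, nv, nuv, M))
        if np.isnan(val):
            continue
        better = (
            best is None
            or (val > best[1] if spec.higher_is_stronger else val < best[1])
        )
        if better:
            cnf = CNFPhenotype(tuple(clause_sets[ci] for ci in combo))
            best = (cnf.canonical(), val,
                    ContingencySummary(nu, nv, nuv, M))
    if best is None:
        raise ValueError("statistic undefined on every candidate CNF")
    return best
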