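import itertools
import math

import numpy as np
import pytest

from revgwas.assoc_stats import fisher_log_pvalue
from revgwas.io_model import (
    BinaryMatrix,
    CNFPhenotype,
    ValidationError,
    collapse_subjects,
    uncollapsed,
)
from revgwas.ilp_core import (
    Solution,
    build_formulation,
    cnf_count,
    enumerate_cnf_oracle,
    evaluate_cnf,
    extract_cnf,
    postprocess_cnf,
    solution_stat_value,
    solve,
)

from conftest import make_pair


def brute_eval(cnf, Y):
    out = []
    for row in np.asarray(Y):
        ok = True
        for clause in cnf.clauses:
            ok = ok and any(row[j] for j in clause)
        out.append(int(ok))
    return out


class TestEvaluateCNF:
    def test_two_clause_example(self):
        # (A or B) and (C or D) over columns A,B,C,D
        cnf = CNFPhenotype((frozenset([0, 1]), frozenset([2, 3])))
        Y = np.array([
            [1, 0, 1, 0],   # A and C -> 1
            [1, 0, 0, 0],   # A only -> 0
            [0, 1, 0, 1],   # B and D -> 1
            [0, 0, 1, 1],   # second clause only -> 0
        ])
        assert evaluate_cnf(cnf, Y).tolist() == [1, 0, 1, 0]

    def test_single_literal_returns_column(self, rng):
        _, Y = make_pair(rng, 15, 1, 3)
        cnf = CNFPhenotype((frozenset([1]),))
        assert evaluate_cnf(cnf, Y).tolist() == Y.values[:, 1].tolist()

    def test_matches_truth_table_oracle(self, rng):
        for _ in range(20):
            M, P = 25, 4
            _, Y = make_pair(rng, M, 1, P)
            k = int(rng.integers(1, 4))
            cnf = CNFPhenotype(tuple(
                frozenset(rng.choice(P, size=rng.integers(1, 3),
                                     replace=False).tolist())
                for _ in range(k)))
            assert evaluate_cnf(cnf, Y).tolist() == brute_eval(cnf, Y.values)


class TestFormulationCounts:
    def test_printed_size_formulas_on_uncollapsed_input(self, rng):
        K, M, P = 2, 10, 4
        while True:  # want O = 12 exactly, matching the worked size example
            X, Y = make_pair(rng, M, 1, P, py=0.3)
            O = int(Y.values.sum())
            if O == 12:
                break
        un = uncollapsed(X, Y)
        f = build_formulation(un.carrier_counts[:, 0], un, K, L=2)
        core_vars = [n for n in f.var_names
                     if n.split("_")[0] in ("U", "Pc", "Pi", "S", "T")]
        assert len(core_vars) == K * (M + P) + M + 2 == 40
        counts = f.constraint_counts()
        n_ineq = counts["or"] + counts["and"] + counts["clause_size"]
        assert n_ineq == K * (2 * M + O + 1) + M == 76
        assert counts["count_eq"] == 2

    def test_formula_holds_across_random_shapes(self, rng):
        for _ in range(5):
            M = int(rng.integers(4, 20))
            P = int(rng.integers(2, 6))
            K = int(rng.integers(1, 4))
            X, Y = make_pair(rng, M, 1, P)
            O = int(Y.values.sum())
            un = uncollapsed(X, Y)
            f = build_formulation(un.carrier_counts[:, 0], un, K, L=2)
            counts = f.constraint_counts()
            assert counts["or"] + counts["and"] + counts["clause_size"] == \
                K * (2 * M + O + 1) + M


class TestSolve:
    def test_all_zero_phenotypes(self, rng):
        M, P = 12, 3
        X, _ = make_pair(rng, M, 1, P)
        Y = BinaryMatrix(np.zeros((M, P), dtype=int), X.row_ids,
                         tuple(f"ph{j}" for j in range(P)))
        c = collapse_subjects(X, Y)
        f = build_formulation(c.carrier_counts[:, 0], c, K=2, L=2,
                              objective="agreement")
        sol = solve(f)
        nv = int(X.values.sum())
        # only the empty combined phenotype exists: agreement = non-carriers
        assert solution_stat_value(f, sol) == pytest.approx(M - nv)

    def test_collapsed_and_uncollapsed_optima_agree(self, rng):
        for _ in range(8):
            M, P = 30, 4
            X, Y = make_pair(rng, M, 1, P)
            col = collapse_subjects(X, Y)
            un = uncollapsed(X, Y)
            vals = []
            for data in (col, un):
                f = build_formulation(data.carrier_counts[:, 0], data,
                                      K=2, L=2, objective="agreement")
                vals.append(solution_stat_value(f, solve(f)))
            assert vals[0] == pytest.approx(vals[1])

    def test_degenerate_cnf_space_is_best_single_phenotype(self, rng):
        M, P = 25, 3
        X, Y = make_pair(rng, M, 1, P)
        c = collapse_subjects(X, Y)
        f = build_formulation(c.carrier_counts[:, 0], c, K=1, L=1,
                              objective="agreement")
        best = max(
            int((Y.values[:, j] == X.values[:, 0]).sum()) for j in range(P)
        )
        assert solution_stat_value(f, solve(f)) == pytest.approx(best)

    @pytest.mark.parametrize("objective", ["agreement", "covariance"])
    def test_optimum_matches_enumeration_oracle(self, rng, objective):
        for _ in range(10):
            M, P = 30, 4
            X, Y = make_pair(rng, M, 1, P)
            c = collapse_subjects(X, Y)
            f = build_formulation(c.carrier_counts[:, 0], c, K=2, L=2,
                                  objective=objective)
            got = solution_stat_value(f, solve(f))
            _, want, _ = enumerate_cnf_oracle(X.values[:, 0], Y, 2, 2,
                                              objective)
            assert got == pytest.approx(want, abs=1e-9)

    def test_unattainable_threshold_is_infeasible(self, rng):
        M, P = 20, 3
        X, Y = make_pair(rng, M, 1, P)
        c = collapse_subjects(X, Y)
        f = build_formulation(c.carrier_counts[:, 0], c, K=1, L=1,
                              objective="feasibility",
                              threshold=-5000.0, threshold_is_log=True)
        assert solve(f).status == "infeasible"

    def test_nonlinear_objective_rejected(self, rng):
        X, Y = make_pair(rng, 10, 1, 2)
        c = collapse_subjects(X, Y)
        with pytest.raises(ValidationError, match="search"):
            build_formulation(c.carrier_counts[:, 0], c, 1, 1,
                              objective="fisher_p")


class TestExtract:
    def test_reads_clauses_and_verifies(self, rng):
        M, P = 20, 4
        X, Y = make_pair(rng, M, 1, P)
        c = collapse_subjects(X, Y)
        f = build_formulation(c.carrier_counts[:, 0], c, K=2, L=2,
                              objective="agreement")
        sol = solve(f)
        cnf = extract_cnf(sol, K=2, L=2, collapsed=c)
        ind = evaluate_cnf(cnf, c.profiles)
        S = int((c.multiplicity * ind).sum())
        assert S == round(sol["S"])

    def test_empty_clause_is_an_error(self):
        sol = Solution("optimal", 0.0, {"U_0_0": 1.0, "U_0_1": 0.0,
                                        "U_1_1": 0.0})
        with pytest.raises(ValidationError, match="empty clause"):
            extract_cnf(sol, K=2, L=1)


class TestPostprocess:
    def test_superset_clause_dropped(self):
        # (A) and (A or B) -> (A)
        cnf = CNFPhenotype((frozenset([0]), frozenset([0, 1])))
        assert postprocess_cnf(cnf).clauses == (frozenset([0]),)

    def test_duplicate_clauses_merged(self):
        cnf = CNFPhenotype((frozenset([0, 1]), frozenset([1, 0])))
        assert postprocess_cnf(cnf).clauses == (frozenset([0, 1]),)

    def test_minimal_cnf_unchanged(self):
        cnf = CNFPhenotype((frozenset([0, 1]), frozenset([2])))
        assert postprocess_cnf(cnf) == cnf.canonical()

    def test_truth_table_equivalence_over_all_profiles(self, rng):
        P = 4
        profiles = np.array(list(itertools.product([0, 1], repeat=P)))
        for _ in range(25):
            k = int(rng.integers(1, 4))
            cnf = CNFPhenotype(tuple(
                frozenset(rng.choice(P, size=rng.integers(1, 4),
                                     replace=False).tolist())
                for _ in range(k)))
            post = postprocess_cnf(cnf)
            assert evaluate_cnf(post, profiles).tolist() == \
                evaluate_cnf(cnf, profiles).tolist()


class TestOracle:
    def test_reduces_to_single_phenotype_scan(self, rng):
        M, P = 30, 3
        X, Y = make_pair(rng, M, 1, P)
        x = X.values[:, 0]
        cnf, val, _ = enumerate_cnf_oracle(x, Y, 1, 1, "fisher_p")
        nv = int(x.sum())
        best = min(
            float(fisher_log_pvalue(int(Y.values[:, j].sum()), nv,
                                    int((Y.values[:, j] & x).sum()), M))
            for j in range(P)
        )
        assert val == pytest.approx(best)
        assert len(cnf.clauses) == 1 and len(cnf.clauses[0]) == 1

    def test_distinct_structure_count_matches_closed_form(self):
        P, K, L = 4, 2, 2
        clauses = [frozenset(c) for c in itertools.combinations(range(P), L)]
        distinct = set()
        for combo in itertools.combinations(clauses, K):
            distinct.add(frozenset(combo))
        assert len(distinct) == cnf_count(P, K, L) == math.comb(
            math.comb(P, L), K)

    def test_guard_refuses_combinatorial_blowups(self, rng):
        _, Y = make_pair(rng, 10, 1, 5)
        x = np.zeros(10, dtype=int)
        with pytest.raises(ValueError, match="guard"):
            enumerate_cnf_oracle(x, Y, 3, 3, "agreement",
                                 max_combinations=10)
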