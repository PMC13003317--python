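import math

import numpy as np
import pytest
from scipy.optimize import linprog

from revgwas.assoc_stats import fisher_log_pvalue
from revgwas.boundary import (
    BoundaryError,
    BoundarySegments,
    encode_lower_bound,
    prune_boundary,
    simplify_boundary,
    threshold_curve,
)


def curve_oracle(nv, M, p0):
    """Linear-scan reference for g(S): smallest attainable T passing p0."""
    g = np.full(M + 1, -1, dtype=int)
    for S in range(M + 1):
        lo, hi = max(0, S + nv - M), min(S, nv)
        for T in range(lo, hi + 1):
            if fisher_log_pvalue(S, nv, T, M) <= math.log(p0) + 1e-12:
                g[S] = T
                break
    return g


def random_cases(rng, n, m_max=60):
    for _ in range(n):
        M = int(rng.integers(8, m_max + 1))
        nv = int(rng.integers(1, M))
        p0 = float(rng.choice([0.5, 0.1, 0.05, 0.01, 0.001]))
        yield nv, M, p0


class TestThresholdCurve:
    def test_vacuous_threshold(self):
        c = threshold_curve(nv=5, M=12, p0=1.0)
        for S in range(13):
            assert c.g[S] == max(0, S + 5 - 12)

    def test_small_example_via_scan(self):
        # M=20, nv=5, p0=0.05: at S=4 the tail first passes at T=3
        assert fisher_log_pvalue(4, 5, 3, 20) <= math.log(0.05)
        assert fisher_log_pvalue(4, 5, 2, 20) > math.log(0.05)
        c = threshold_curve(nv=5, M=20, p0=0.05)
        assert c.g[4] == 3

    def test_matches_linear_scan_oracle(self, rng):
        for nv, M, p0 in random_cases(rng, 12, m_max=40):
            c = threshold_curve(nv, M, p0)
            assert c.g.tolist() == curve_oracle(nv, M, p0).tolist(), \
                (nv, M, p0)

    def test_non_monotone_statistic_rejected(self):
        with pytest.raises(BoundaryError, match="monotone"):
            threshold_curve(5, 20, 0.05, spec="chi2")


class TestPrune:
    def test_constant_level_keeps_two_points(self):
        c = threshold_curve(nv=5, M=12, p0=1.0)
        # restrict to the S-range where g is the constant 0
        R = prune_boundary(c)
        levels = {}
        for s, g in R:
            levels.setdefault(g, []).append(s)
        # leftmost point plus one max-S point per level
        assert R[0] == (0, 0)
        for g, ss in levels.items():
            assert len(ss) <= 2

    def test_classification_matches_full_boundary(self, rng):
        for nv, M, p0 in random_cases(rng, 15, m_max=40):
            c = threshold_curve(nv, M, p0)
            R = prune_boundary(c)
            if not R:
                continue
            by_g = {}
            for s, g in R:
                by_g[g] = max(by_g.get(g, s), s)

            def g_from_R(S):
                # step reconstruction: smallest level whose range reaches S
                for g in sorted(by_g):
                    if S <= by_g[g]:
                        return g
                return None

            s_lo = R[0][0]
            s_hi = max(s for s, _ in R)
            for S in range(s_lo, s_hi + 1):
                assert g_from_R(S) == c.g[S], (nv, M, p0, S)

    def test_fully_infeasible_curve_gives_empty_result(self):
        c = threshold_curve(nv=1, M=10, p0=1e-6)
        assert prune_boundary(c) == []


def dp_min_segments(points, w):
    """Exhaustive DP: minimum number of segments covering the levels in
    order, each fitting the corridor [g, g+w] over its levels (independent
    LP feasibility check)."""
    from revgwas.boundary import _levels_from_points

    levels = _levels_from_points(sorted(points))
    n = len(levels)

    def window_ok(i, j):
        A_ub, b_ub = [], []
        for s_l, s_r, g in levels[i:j]:
            for s in {s_l, s_r}:
                A_ub.append([s, 1.0])
                b_ub.append(g + w)
                A_ub.append([-s, -1.0])
                b_ub.append(-g)
        res = linprog([0, 0], A_ub=A_ub, b_ub=b_ub,
                      bounds=[(None, None)] * 2, method="highs")
        return res.success

    INF = 10**9
    best = [INF] * (n + 1)
    best[0] = 0
    for j in range(1, n + 1):
        for i in range(j):
            if best[i] + 1 < best[j] and window_ok(i, j):
                best[j] = best[i] + 1
    return best[n]


class TestSimplify:
    def test_collinear_points_need_one_segment(self):
        R = [(0, 0), (1, 1), (2, 2), (3, 3)]
        b = simplify_boundary(R, delta=0.001)
        assert b.k == 1

    def test_minimum_segment_count_matches_dp_oracle(self, rng):
        cases = [[(0, 0), (1, 0), (2, 1), (3, 1)]]
        for nv, M, p0 in random_cases(rng, 8, m_max=40):
            c = threshold_curve(nv, M, p0)
            R = prune_boundary(c)
            if R:
                cases.append(R)
        for R in cases:
            b = simplify_boundary(R, delta=0.001)
            assert b.k == dp_min_segments(R, b.w), R

    def test_segment_count_non_increasing_as_delta_shrinks(self, rng):
        c = threshold_curve(nv=13, M=40, p0=0.05)
        R = prune_boundary(c)
        ks = [simplify_boundary(R, delta=d).k for d in (0.5, 0.1, 0.001)]
        assert ks == sorted(ks, reverse=True)

    def test_single_point_gives_degenerate_segment(self):
        b = simplify_boundary([(4, 2)], delta=0.001)
        assert b.k == 1
        assert b.ghat(4) == pytest.approx(2, abs=1 - b.delta)

    def test_corridor_holds_at_every_level_point(self, rng):
        for nv, M, p0 in random_cases(rng, 10, m_max=50):
            c = threshold_curve(nv, M, p0)
            R = prune_boundary(c)
            if not R:
                continue
            b = simplify_boundary(R)
            s_lo, s_hi = b.s_range
            for S in range(s_lo, s_hi + 1):
                assert c.g[S] - 1e-9 <= b.ghat(S) <= c.g[S] + b.w + 1e-9


def solve_fragment(segments, S, T):
    """Independent check of the emitted encoding: fix S and T, solve the
    fragment as a MILP."""
    from revgwas.ilp_core import Formulation, solve

    enc = encode_lower_bound(segments)
    f = Formulation()
    f.add_var("S", S, S, integer=True)
    f.add_var("T", T, T, integer=True)
    for name, lb, ub, isint in enc.aux_vars:
        f.add_var(name, lb, ub, integer=isint)
    for coeffs, lb, ub in enc.constraints:
        f.add_constraint(coeffs, lb=lb, ub=ub)
    f.set_objective({}, sense="max")
    return solve(f).status == "optimal"


class TestEncode:
    def test_identity_line_single_halfplane(self):
        seg = BoundarySegments(((0, 20, 1.0, 0.0),), delta=0.001, nv=20, M=20)
        enc = encode_lower_bound(seg)
        assert enc.convex and enc.n_aux_vars == 0
        for S in range(21):
            for T in range(21):
                assert seg.feasible_pair(S, T) == (T >= S)

    @pytest.mark.parametrize("segments,label", [
        (((0, 5, 0.0, 0.0), (5, 10, 2.0, -10.0)), "convex corner"),
        (((0, 5, 2.0, 0.0), (6, 10, 0.0, 10.0)), "concave corner"),
    ])
    def test_two_segment_corner_grid_equivalence(self, segments, label):
        seg = BoundarySegments(segments, delta=0.001, nv=30, M=10)

        def direct(S, T):
            for s_lo, s_hi, a, b in segments:
                if s_lo <= S <= s_hi:
                    return T >= a * S + b - seg.margin
            return False

        enc = encode_lower_bound(seg)
        if label == "concave corner":
            assert not enc.convex and enc.n_aux_vars == 2 * seg.k
            assert enc.n_constraints == 2 * seg.k + 3
        for S in range(0, 11):
            for T in range(0, 25):
                assert seg.feasible_pair(S, T) == direct(S, T), (S, T)
        # cross-check the MILP fragment itself on a sample of points
        for S in range(0, 11, 2):
            for T in range(0, 25, 3):
                assert solve_fragment(seg, S, T) == direct(S, T), (S, T, label)

    def test_empty_segments_rejected(self):
        seg = BoundarySegments((), delta=0.001, nv=5, M=5)
        with pytest.raises(BoundaryError):
            encode_lower_bound(seg)


class TestEndToEnd:
    def test_integer_feasibility_equals_direct_threshold(self, rng):
        """Random boundaries: the encoded feasible set equals the exact
        fisher_p <= p0 test on every attainable integer pair."""
        checked = 0
        for nv, M, p0 in random_cases(rng, 15, m_max=60):
            c = threshold_curve(nv, M, p0)
            R = prune_boundary(c)
            if not R:
                continue
            b = simplify_boundary(R)
            lnp0 = math.log(p0) + 1e-12
            for S in range(M + 1):
                lo, hi = max(0, S + nv - M), min(S, nv)
                for T in range(lo, hi + 1):
                    direct = fisher_log_pvalue(S, nv, T, M) <= lnp0
                    assert b.feasible_pair(S, T) == direct, (nv, M, p0, S, T)
            checked += 1
        assert checked >= 10
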