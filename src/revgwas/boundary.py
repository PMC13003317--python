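"""Threshold boundaries: level curves of a monotone statistic as linear
constraints.

A threshold on a non-linear but nuv-monotone statistic (pass iff
``fisher_p(S, T) <= p0``) is equivalent, for each combined-phenotype
prevalence ``S``, to a lower bound ``T >= g(S)`` on the co-occurrence count,
where ``g`` is the level curve of the statistic at the threshold.  This
module computes ``g`` by binary search over hypergeometric tails, prunes it
to its level endpoints, replaces it with a minimum-segment piecewise-linear
surrogate ``ghat`` inside a corridor of width ``w = 1 - delta``, and emits a
linear encoding of ``T >= ghat(S) - w`` suitable for a MILP.

Exactness on the integer lattice: each segment's line ``l`` satisfies
``g(S) <= l(S) <= g(S) + w`` at *every* integer S it covers (the corridor is
enforced at both endpoints of every level of the step function g, and g is
constant between them).  Hence for integer T,

    T >= l(S) - w  <=>  T >= g(S),

because ``g(S) - 1 < g(S) - w <= l(S) - w <= g(S)``.  The surrogate therefore
admits exactly the integer points that pass the threshold, for any
``0 < delta < 1``; delta only trades segment count against the numerical
margin of the separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .assoc_stats import STATS, StatSpec, compute_stat, fisher_log_pvalue

__all__ = [
    "BoundaryError",
    "ThresholdCurve",
    "BoundarySegments",
    "BoundaryEncoding",
    "threshold_curve",
    "prune_boundary",
    "simplify_boundary",
    "encode_lower_bound",
]

DEFAULT_DELTA = 0.001


class BoundaryError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdCurve:
    """g(S) for S in [0, M]: the smallest attainable T passing the threshold,
    or -1 where no attainable T passes."""

    nv: int
    M: int
    p0: float
    g: np.ndarray  # int64, length M+1, -1 = infeasible

    @property
    def feasible(self) -> np.ndarray:
        return self.g >= 0

    def feasible_range(self) -> tuple[int, int]:
        idx = np.flatnonzero(self.feasible)
        if idx.size == 0:
            raise BoundaryError("threshold is unattainable for every S")
        return int(idx[0]), int(idx[-1])

    def passes(self, S: int, T: int) -> bool:
        """Direct check: is the integer pair (S, T) on or above the curve?"""
        return self.g[S] >= 0 and T >= self.g[S]


@dataclass(frozen=True)
class BoundarySegments:
    """Piecewise-linear surrogate ghat as ordered (S_start, S_end, slope,
    intercept) segments partitioning the feasible S-range."""

    segments: tuple[tuple[int, int, float, float], ...]
    delta: float
    nv: int
    M: int

    @property
    def k(self) -> int:
        return len(self.segments)

    @property
    def w(self) -> float:
        return 1.0 - self.delta

    @property
    def s_range(self) -> tuple[int, int]:
        return self.segments[0][0], self.segments[-1][1]

    def ghat(self, S: float) -> float:
        for s_lo, s_hi, a, b in self.segments:
            if s_lo <= S <= s_hi:
                return a * S + b
        raise BoundaryError(f"S={S} outside the boundary domain {self.s_range}")

    @property
    def margin(self) -> float:
        """Separation margin used by the encoding: w plus half of delta.

        Points strictly below the boundary sit at least a full delta under
        ``ghat - w``, so borrowing delta/2 as numerical headroom cannot
        admit them, while points on the boundary (where ``ghat`` may touch
        ``g + w`` exactly) are kept clear of floating-point round-off.
        """
        return self.w + 0.5 * self.delta

    def feasible_pair(self, S: int, T: int) -> bool:
        """Semantics of the emitted encoding: S inside the domain and
        T >= ghat(S) - margin."""
        s_lo, s_hi = self.s_range
        if not s_lo <= S <= s_hi:
            return False
        return T >= self.ghat(S) - self.margin


@dataclass(frozen=True)
class BoundaryEncoding:
    """MILP fragment enforcing T >= ghat(S) - w within the S-domain.

    ``aux_vars`` are (name, lb, ub, integer) tuples; ``constraints`` are
    (coefficients, lb, ub) with coefficient keys naming "S", "T" or an aux
    variable.  ``convex`` marks the cheap half-plane-only encoding.
    """

    aux_vars: tuple = ()
    constraints: tuple = ()
    convex: bool = True
    s_range: tuple[int, int] = (0, 0)

    @property
    def n_aux_vars(self) -> int:
        return len(self.aux_vars)

    @property
    def n_constraints(self) -> int:
        return len(self.constraints)


def threshold_curve(nv: int, M: int, p0: float,
                    spec: StatSpec | str = "fisher_p",
                    direction: str = "over",
                    log: bool = False) -> ThresholdCurve:
    """Level curve of a monotone statistic at threshold p0.

    For ``fisher_p`` the pass condition is ``p <= p0`` and g(S) is found by a
    vectorised binary search over the attainable T range (the p-value is
    monotone decreasing in T).  For other monotone statistics the pass
    condition is ``stat >= p0`` (increasing) or ``stat <= p0`` (decreasing).
    Non-monotone statistics (chi2) are rejected: their pass set in T is not
    an upper interval, so no single lower bound g(S) represents it.

    With ``log=True`` the fisher threshold ``p0`` is interpreted as a natural
    log p-value, allowing thresholds far below double-precision underflow.
    """
    if isinstance(spec, str):
        spec = STATS[spec]
    if spec.monotone_in_nuv == "non-monotone":
        raise BoundaryError(
            f"statistic {spec.name!r} is not monotone in nuv; a threshold on "
            "it is not expressible as a lower boundary T >= g(S)"
        )
    if spec.name == "fisher_p":
        if log and p0 > 0:
            raise BoundaryError("a log p-value threshold must be <= 0")
        if not log and not 0 < p0 <= 1:
            raise BoundaryError("p0 must be in (0, 1]")
    S = np.arange(M + 1)
    t_min = np.maximum(0, S + nv - M)
    t_max = np.minimum(S, nv)

    if spec.name == "fisher_p" and direction == "over":
        log_p0 = p0 if log else np.log(p0)
        g = _fisher_curve_fast(nv, M, log_p0)
        return ThresholdCurve(nv=nv, M=M, p0=p0, g=g)

    if spec.name == "fisher_p":
        log_p0 = p0 if log else np.log(p0)

        def pass_at(s_arr, t_arr):
            return fisher_log_pvalue(s_arr, nv, t_arr, M, direction) <= log_p0 + 1e-12

    else:
        from .assoc_stats import ContingencySummary

        def pass_at(s_arr, t_arr):
            out = np.empty(len(s_arr), dtype=bool)
            for i, (s, t) in enumerate(zip(s_arr, t_arr)):
                val = compute_stat(spec, ContingencySummary(int(s), nv, int(t), M))
                ok = val >= p0 if spec.higher_is_stronger else val <= p0
                out[i] = bool(ok) and not np.isnan(val)
            return out

    # The strongest attainable value sits at t_max; infeasible S fail there.
    feasible = pass_at(S, t_max)
    lo = t_min.copy()
    hi = t_max.copy()
    active = feasible.copy()
    while np.any(active & (lo < hi)):
        mid = (lo + hi) // 2
        probe = active & (lo < hi)
        ok = np.zeros(M + 1, dtype=bool)
        ok[probe] = pass_at(S[probe], mid[probe])
        hi = np.where(probe & ok, mid, hi)
        lo = np.where(probe & ~ok, mid + 1, lo)
    g = np.where(feasible, lo, -1).astype(np.int64)
    return ThresholdCurve(nv=nv, M=M, p0=p0, g=g)


def _fisher_curve_fast(nv: int, M: int, log_p0: float,
                       chunk: int = 4000) -> np.ndarray:
    """Vectorised g(S) for the over-representation Fisher tail.

    Computes the full log-pmf table of Hypergeom(M, S, nv) over T = 0..nv via
    gammaln, accumulates upper tails with logaddexp from the right, and takes
    the first T whose tail drops to the threshold.  Chunked over S to bound
    memory at biobank scale.
    """
    from scipy.stats import hypergeom

    g = np.full(M + 1, -1, dtype=np.int64)
    T = np.arange(nv + 1)
    for start in range(0, M + 1, chunk):
        stop = min(start + chunk, M + 1)
        S = np.arange(start, stop)
        logpmf = hypergeom.logpmf(T[None, :], M, S[:, None], nv)
        # upper tail: logsf_row[t] = log P(X >= t)
        tail = np.logaddexp.accumulate(logpmf[:, ::-1], axis=1)[:, ::-1]
        ok = tail <= log_p0 + 1e-12
        t_min = np.maximum(0, S + nv - M)
        t_max = np.minimum(S, nv)
        rows = np.arange(stop - start)
        feas = ok[rows, t_max]          # strongest attainable value passes?
        first = np.maximum(np.argmax(ok, axis=1), t_min)
        g[start:stop] = np.where(feas, first, -1)
    return g


def prune_boundary(curve: ThresholdCurve) -> list[tuple[int, int]]:
    """Reduce the boundary to its leftmost point plus, for each distinct
    feasible g-level, the maximum-S point attaining it.

    An integer point lies below the full boundary iff it lies below this
    reduced set (g is reconstructed exactly by its level right-endpoints on a
    contiguous domain).  Returns [] with a warning-free empty result when no
    S is feasible.
    """
    idx = np.flatnonzero(curve.feasible)
    if idx.size == 0:
        return []
    s_lo, s_hi = int(idx[0]), int(idx[-1])
    if idx.size != s_hi - s_lo + 1:
        raise BoundaryError("feasible S-range is not contiguous")
    gvals = curve.g[s_lo:s_hi + 1]
    if np.any(np.diff(gvals) < 0):
        raise BoundaryError("g(S) is not non-decreasing on its feasible range")
    points = [(s_lo, int(gvals[0]))]
    # last S of each run of equal g
    ends = np.flatnonzero(np.r_[np.diff(gvals) != 0, True])
    for e in ends:
        pt = (s_lo + int(e), int(gvals[e]))
        if pt != points[-1]:
            points.append(pt)
    return points


def _levels_from_points(R: list[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """Rebuild the step function's levels (S_left, S_right, g) from the
    pruned point set."""
    levels: list[tuple[int, int, int]] = []
    by_g: dict[int, int] = {}
    for s, g in R:
        by_g[g] = max(by_g.get(g, s), s)
    s_left = R[0][0]
    for g in sorted(by_g):
        s_right = by_g[g]
        levels.append((s_left, s_right, g))
        s_left = s_right + 1
    return levels


def _corridor_lp(levels, w, minimize=True):
    """Find a line a*S + b with g <= line <= g + w over every level's full
    S-range (endpoint constraints suffice on a linear function).  Returns
    (a, b) or None if infeasible."""
    rows, lo, hi = [], [], []
    pts = []
    for s_l, s_r, g in levels:
        for s in {s_l, s_r}:
            pts.append((s, g))
    A_ub, b_ub = [], []
    for s, g in pts:
        A_ub.append([s, 1.0])
        b_ub.append(g + w)
        A_ub.append([-s, -1.0])
        b_ub.append(-g)
    c = [sum(p[0] for p in pts), len(pts)] if minimize else [0.0, 0.0]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=[(None, None), (None, None)],
                  method="highs")
    if not res.success:
        return None
    return float(res.x[0]), float(res.x[1])


def simplify_boundary(R: list[tuple[int, int]], delta: float = DEFAULT_DELTA,
                      nv: int | None = None, M: int | None = None
                      ) -> BoundarySegments:
    """Minimum-segment piecewise-linear surrogate of the pruned boundary.

    Greedy minimum-link corridor simplification: repeatedly extend a window
    of whole levels as long as a single line fits the corridor
    ``[g, g + w]`` over every level in the window, then emit the longest
    feasible window as one segment.  Window feasibility is prefix-closed
    (adding a level only adds constraints), so maximal windows give the
    minimum number of segments at level granularity.  Each window's line is
    the corridor-feasible line minimising its total height over the
    constraint points, keeping the surrogate snug against the boundary.
    """
    if not R:
        raise BoundaryError("cannot simplify an empty boundary")
    if not 0 < delta < 1:
        raise BoundaryError("delta must be in (0, 1)")
    w = 1.0 - delta
    levels = _levels_from_points(sorted(R))
    if nv is None:
        nv = max(g for _, _, g in levels)
    if M is None:
        M = levels[-1][1]
    segments = []
    i = 0
    n = len(levels)
    while i < n:
        # doubling then bisection on the window end (exclusive)
        j = i + 1
        step = 1
        while j + step <= n and _corridor_lp(levels[i:j + step], w,
                                             minimize=False) is not None:
            j += step
            step *= 2
        lo, hi = j, min(n, j + step - 1)
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if _corridor_lp(levels[i:mid], w, minimize=False) is not None:
                lo = mid
            else:
                hi = mid - 1
        window = levels[i:lo]
        line = _corridor_lp(window, w, minimize=True)
        if line is None:  # single level always fits: horizontal line
            s_l, s_r, g = levels[i]
            segments.append((s_l, s_r, 0.0, float(g)))
            i += 1
            continue
        a, b = line
        segments.append((window[0][0], window[-1][1], a, b))
        i = lo
    return BoundarySegments(segments=tuple(segments), delta=delta, nv=nv, M=M)


def _is_convex_cover(bounds: BoundarySegments) -> bool:
    """True when taking ALL segment half-planes jointly (T >= l_s(S) - w for
    every s) admits exactly the same integer set: no line may rise above
    g(S) at any covered integer S.  Checked at segment endpoints of every
    segment against every line (linear => endpoints suffice)."""
    for s_lo, s_hi, a, b in bounds.segments:
        for s, own in ((s_lo, a * s_lo + b), (s_hi, a * s_hi + b)):
            # other lines must stay on or below the covering line at every
            # integer S of this segment (both are linear: endpoints suffice);
            # then line2 - w <= own - w <= g(S) and no pass-point is cut off.
            for a2, b2 in [(seg[2], seg[3]) for seg in bounds.segments]:
                if a2 * s + b2 > own + 1e-9:
                    return False
    return True


def encode_lower_bound(bounds: BoundarySegments,
                       prefix: str = "bnd") -> BoundaryEncoding:
    """Linear MILP fragment for T >= ghat(S) - w over the boundary domain.

    Convex case (no segment line cuts above another segment's corridor): one
    half-plane per segment plus two S-domain constraints — k + 2 constraints,
    no auxiliary variables.  General case: a binary selector z_s per segment
    with a localised S-copy y_s (y_s = S when segment s is active, else 0),
    giving 2k auxiliary variables and 2k + 3 constraints.  Big-M values are
    the segment S-ranges themselves, the tightest valid choice.
    """
    if bounds.k == 0:
        raise BoundaryError("no segments to encode")
    w = bounds.margin
    s_lo, s_hi = bounds.s_range
    if _is_convex_cover(bounds):
        constraints = [({"S": 1.0}, s_lo, s_hi)]
        for _, _, a, b in bounds.segments:
            # T - a*S >= b - w
            constraints.append(({"T": 1.0, "S": -a}, b - w, None))
        return BoundaryEncoding(aux_vars=(), constraints=tuple(constraints),
                                convex=True, s_range=(s_lo, s_hi))
    aux, cons = [], []
    zsum = {}
    scopy = {"S": -1.0}
    tline = {"T": 1.0}
    for idx, (a_lo, a_hi, a, b) in enumerate(bounds.segments):
        z = f"{prefix}_z{idx}"
        y = f"{prefix}_y{idx}"
        aux.append((z, 0, 1, True))
        aux.append((y, 0, a_hi, False))
        zsum[z] = 1.0
        scopy[y] = 1.0
        # y in [a_lo * z, a_hi * z]
        cons.append(({y: 1.0, z: -float(a_lo)}, 0.0, None))
        cons.append(({y: 1.0, z: -float(a_hi)}, None, 0.0))
        tline[y] = tline.get(y, 0.0) - a
        tline[z] = tline.get(z, 0.0) - (b - w)
    cons.append((zsum, 1.0, 1.0))          # exactly one active segment
    cons.append((scopy, 0.0, 0.0))         # sum of y_s equals S
    cons.append((tline, 0.0, None))        # T >= a*y + (b - w)*z
    return BoundaryEncoding(aux_vars=tuple(aux), constraints=tuple(cons),
                            convex=False, s_range=(s_lo, s_hi))
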