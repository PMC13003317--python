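"""Association statistics computed from a 2x2 contingency summary.

Every statistic supported here is a function of four counts only:

* ``nu``  — subjects with the (combined) phenotype,
* ``nv``  — subjects carrying the variant,
* ``nuv`` — subjects with both,
* ``M``   — total subjects,

equivalently of the 2x2 cells ``a = nuv``, ``b = nu - nuv``, ``c = nv - nuv``,
``d = M - nu - nv + nuv``.  This sufficiency is what lets the optimisation
work on collapsed data: the integer variables S (= nu of the combined
phenotype) and T (= nuv) carry everything the objective or threshold needs.

The one-sided Fisher exact p-value is the upper tail of the hypergeometric
distribution, ``P(X >= nuv)`` with ``X ~ Hypergeom(M, nu, nv)``; it is
monotone decreasing in ``nuv`` for fixed margins, which the threshold-boundary
machinery relies on.  Log-space variants are provided because p-values on
biobank-scale inputs underflow double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "ContingencySummary",
    "StatSpec",
    "STATS",
    "compute_stat",
    "fisher_log_pvalue",
    "fisher_pvalue",
    "fisher_p_monotone_check",
    "summary_from_vectors",
    "cmh_test",
]

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ContingencySummary:
    """Sufficient counts (nu, nv, nuv, M) for a pair of binary vectors."""

    nu: int
    nv: int
    nuv: int
    M: int

    def __post_init__(self):
        a, b, c, d = self.cells
        if min(a, b, c, d) < 0 or self.M <= 0:
            raise ValueError(
                f"invalid contingency summary nu={self.nu} nv={self.nv} "
                f"nuv={self.nuv} M={self.M}"
            )

    @property
    def cells(self) -> tuple[int, int, int, int]:
        a = self.nuv
        b = self.nu - self.nuv
        c = self.nv - self.nuv
        d = self.M - self.nu - self.nv + self.nuv
        return a, b, c, d


@dataclass(frozen=True)
class StatSpec:
    """Descriptor of one association statistic.

    ``higher_is_stronger`` gives the direction in which the statistic means
    stronger association; ``monotone_in_nuv`` is one of ``"increasing"``,
    ``"decreasing"`` or ``"non-monotone"`` (for fixed nu, nv, M);
    ``linear`` marks the statistics affine in (nu, nuv), which can be used
    directly as ILP objectives.
    """

    name: str
    higher_is_stronger: bool
    monotone_in_nuv: str
    linear: bool = False


STATS: dict[str, StatSpec] = {
    "agreement": StatSpec("agreement", True, "increasing", linear=True),
    "hamming": StatSpec("hamming", False, "decreasing", linear=True),
    "covariance": StatSpec("covariance", True, "increasing", linear=True),
    "correlation": StatSpec("correlation", True, "increasing"),
    "chi2": StatSpec("chi2", True, "non-monotone"),
    "odds_ratio": StatSpec("odds_ratio", True, "increasing"),
    "kappa": StatSpec("kappa", True, "increasing"),
    "fisher_p": StatSpec("fisher_p", False, "decreasing"),
}


def fisher_log_pvalue(nu, nv, nuv, M, direction: str = "over"):
    """Natural log of the one-sided Fisher exact p-value.

    ``direction="over"`` tests over-representation, p = P(X >= nuv);
    ``direction="under"`` tests the protective side, p = P(X <= nuv).
    Vectorised over the count arguments.
    """
    if direction == "over":
        return hypergeom.logsf(np.asarray(nuv) - 1, M, nu, nv)
    if direction == "under":
        return hypergeom.logcdf(nuv, M, nu, nv)
    raise ValueError(f"unknown direction {direction!r}")


def fisher_pvalue(nu, nv, nuv, M, direction: str = "over"):
    p = np.exp(fisher_log_pvalue(nu, nv, nuv, M, direction))
    return np.minimum(p, 1.0)


def compute_stat(spec: StatSpec | str, t: ContingencySummary) -> float:
    """Evaluate one statistic on a contingency summary.

    Returns NaN where the statistic is undefined (a zero-variance margin for
    correlation/chi2/kappa) and +inf for an odds ratio with an empty
    discordant product.
    """
    if isinstance(spec, str):
        spec = STATS[spec]
    a, b, c, d = t.cells
    nu, nv, M = t.nu, t.nv, t.M
    name = spec.name
    if name == "agreement":
        return float(a + d)
    if name == "hamming":
        return float(b + c)
    if name == "covariance":
        return a / M - (nu * nv) / M**2
    degenerate = nu in (0, M) or nv in (0, M)  # a zero-variance margin
    if name == "correlation":
        if degenerate:
            return UNDEFINED
        return (M * a - nu * nv) / math.sqrt(nu * (M - nu) * nv * (M - nv))
    if name == "chi2":
        if degenerate:
            return UNDEFINED
        return M * (a * d - b * c) ** 2 / (nu * nv * (M - nu) * (M - nv))
    if name == "odds_ratio":
        if b * c == 0:
            return math.inf if a * d > 0 else UNDEFINED
        return (a * d) / (b * c)
    if name == "kappa":
        denom = nu * (M - nv) + nv * (M - nu)
        if degenerate or denom == 0:
            return UNDEFINED
        return 2 * (a * d - b * c) / denom
    if name == "fisher_p":
        return float(fisher_pvalue(nu, nv, t.nuv, M))
    raise ValueError(f"unknown statistic {name!r}")


def attainable_nuv_range(nu: int, nv: int, M: int) -> tuple[int, int]:
    """Range of nuv values realisable by some pair of vectors with the given
    margins: [max(0, nu+nv-M), min(nu, nv)]."""
    return max(0, nu + nv - M), min(nu, nv)


def fisher_p_monotone_check(nu: int, nv: int, M: int,
                            direction: str = "over") -> bool:
    """True iff the Fisher p-value is non-increasing as nuv scans its
    attainable range.  Test utility; scans every attainable value."""
    lo, hi = attainable_nuv_range(nu, nv, M)
    nuvs = np.arange(lo, hi + 1)
    logp = fisher_log_pvalue(nu, nv, nuvs, M, direction)
    return bool(np.all(np.diff(logp) <= 1e-12))


def summary_from_vectors(u, v) -> ContingencySummary:
    """Build the sufficient counts directly from two binary vectors."""
    u = np.asarray(u, dtype=np.int64)
    v = np.asarray(v, dtype=np.int64)
    if u.shape != v.shape:
        raise ValueError("vectors have different lengths")
    return ContingencySummary(
        nu=int(u.sum()), nv=int(v.sum()), nuv=int((u & v).sum()), M=u.size
    )


def cmh_test(x_col, combined, best_single) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel chi-square test (1 df, no continuity
    correction) of variant vs combined phenotype, stratified by the best
    single phenotype.

    The combined phenotype may be significant only because it inherits the
    association of its strongest single component; stratifying on that
    component asks whether any association remains beyond it.  Returns
    ``(statistic, p_value)``; both are NaN when every stratum is degenerate
    (zero margin), e.g. when the stratifier equals the combined phenotype.
    """
    from scipy.stats import chi2 as chi2_dist

    x = np.asarray(x_col, dtype=np.int64)
    u = np.asarray(combined, dtype=np.int64)
    s = np.asarray(best_single, dtype=np.int64)
    if not (x.shape == u.shape == s.shape):
        raise ValueError("vectors have different lengths")
    num = 0.0
    var = 0.0
    informative = False
    for level in (0, 1):
        mask = s == level
        n = int(mask.sum())
        if n < 2:
            continue
        a = int((x[mask] & u[mask]).sum())
        r1 = int(x[mask].sum())       # variant carriers in stratum
        c1 = int(u[mask].sum())       # phenotype positives in stratum
        if r1 in (0, n) or c1 in (0, n):
            continue                  # zero margin: contributes nothing
        informative = True
        num += a - r1 * c1 / n
        var += r1 * (n - r1) * c1 * (n - c1) / (n**2 * (n - 1))
    if not informative or var == 0:
        return UNDEFINED, UNDEFINED
    stat = num**2 / var
    return float(stat), float(chi2_dist.sf(stat, df=1))
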