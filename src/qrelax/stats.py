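"""Test-selection battery for condition comparisons.

The longitudinal design compares 19 migraine-free days against 2 migraine
days, so the group sizes are severely unbalanced and one group is far too
small for asymptotic machinery.  The battery therefore:

* gates on normality with Shapiro–Wilk, forcing the nonparametric route
  whenever any group has n < 3 (the test is undefined there);
* uses Welch's t (unequal variances) on the parametric route;
* uses a two-sided Mann–Whitney U with an EXACT null distribution obtained
  by complete enumeration of rank assignments on the nonparametric route —
  with n_a * n_b <= 400 the C(n_a + n_b, n_b) enumeration is cheap and
  exactness makes the p-value independently checkable.  Ties are handled
  with mid-ranks; the enumerated null conditions on the observed (tied)
  rank multiset, i.e. it is the exact permutation distribution of U.
* adjusts families of p-values by Bonferroni (multiply by the family size,
  cap at 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "normality_gate",
    "two_sample_compare",
    "exact_mannwhitney",
    "multi_group",
    "bonferroni_adjust",
]

ENUM_LIMIT = 400  # max n_a * n_b for complete enumeration


@dataclass
class StatResult:
    test_used: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    p_adjusted: float | None = None
    degenerate: bool = False


def _as_groups(*groups) -> list[np.ndarray]:
    out = []
    for g in groups:
        a = np.asarray(g, dtype=float).ravel()
        if a.size == 0:
            raise ValueError("empty group")
        out.append(a)
    return out


def normality_gate(group_a, group_b, alpha: float = 0.05) -> str:
    """Choose the test family: ``"parametric"`` or ``"nonparametric"``.

    Shapiro–Wilk is applied to each group with n >= 3.  If any testable
    group rejects normality at ``alpha``, or any group is too small to
    test (n < 3), the nonparametric route is chosen.
    """
    a, b = _as_groups(group_a, group_b)
    for g in (a, b):
        if g.size < 3:
            return "nonparametric"
        if np.ptp(g) == 0:
            # constant sample: Shapiro-Wilk undefined, clearly non-normal
            return "nonparametric"
        if sps.shapiro(g).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def exact_mannwhitney(a, b) -> StatResult:
    """Two-sided Mann–Whitney U with exact enumeration p-value.

    U is computed for group ``b`` from mid-ranks of the pooled sample.  The
    null distribution is built by enumerating all C(n, n_b) assignments of
    the pooled ranks to group b; the two-sided p is
    2 * min(P(U <= u), P(U >= u)) capped at 1.
    """
    a, b = _as_groups(a, b)
    na, nb = a.size, b.size
    if na * nb > ENUM_LIMIT:
        raise ValueError(
            f"enumeration limited to n_a*n_b <= {ENUM_LIMIT}; got {na * nb}"
        )
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return StatResult("mann_whitney_exact", float(na * nb / 2), 1.0,
                          (na, nb), degenerate=True)
    ranks = sps.rankdata(pooled)  # mid-ranks for ties
    offset = nb * (nb + 1) / 2
    u_obs = ranks[na:].sum() - offset
    n = na + nb
    total = math.comb(n, nb)
    count_le = 0
    count_ge = 0
    eps = 1e-9
    for idx in combinations(range(n), nb):
        u = ranks[list(idx)].sum() - offset
        if u <= u_obs + eps:
            count_le += 1
        if u >= u_obs - eps:
            count_ge += 1
    p = min(1.0, 2.0 * min(count_le, count_ge) / total)
    return StatResult("mann_whitney_exact", float(u_obs), p, (na, nb))


def two_sample_compare(a, b, route: str | None = None, alpha: float = 0.05) -> StatResult:
    """Compare two samples with the route chosen by :func:`normality_gate`.

    Parametric route: two-sided Welch t-test.  Nonparametric route: exact
    two-sided Mann–Whitney U.  Degenerate data (every value identical in
    both groups) yields p = 1 with a flag.
    """
    ga, gb = _as_groups(a, b)
    if route is None:
        route = normality_gate(ga, gb, alpha=alpha)
    if route not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown route {route!r}")
    if np.ptp(np.concatenate([ga, gb])) == 0:
        return StatResult("degenerate", 0.0, 1.0, (ga.size, gb.size), degenerate=True)
    if route == "parametric":
        if min(ga.size, gb.size) < 2:
            raise ValueError("parametric route needs n >= 2 per group")
        res = sps.ttest_ind(ga, gb, equal_var=False)
        return StatResult("welch_t", float(res.statistic), float(res.pvalue),
                          (ga.size, gb.size))
    return exact_mannwhitney(ga, gb)


def multi_group(groups, route: str | None = None, alpha: float = 0.05):
    """One-way comparison of >= 2 groups with Bonferroni post-hoc pairs.

    Parametric route: one-way ANOVA; nonparametric: Kruskal–Wallis.  If
    ``route`` is None it is nonparametric as soon as any pairwise gate says
    so.  Returns ``(omnibus, posthoc)`` where posthoc is a list of
    ``(i, j, StatResult)`` with Bonferroni-adjusted p over the pair family.
    """
    gs = _as_groups(*groups)
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if route is None:
        route = "parametric"
        for i, j in combinations(range(len(gs)), 2):
            if normality_gate(gs[i], gs[j], alpha=alpha) == "nonparametric":
                route = "nonparametric"
                break
    pooled = np.concatenate(gs)
    ns = tuple(g.size for g in gs)
    if np.ptp(pooled) == 0:
        omnibus = StatResult("degenerate", 0.0, 1.0, ns, degenerate=True)
        return omnibus, []
    if route == "parametric":
        res = sps.f_oneway(*gs)
        omnibus = StatResult("anova", float(res.statistic), float(res.pvalue), ns)
    else:
        res = sps.kruskal(*gs)
        omnibus = StatResult("kruskal_wallis", float(res.statistic), float(res.pvalue), ns)
    pairs = list(combinations(range(len(gs)), 2))
    raw = [two_sample_compare(gs[i], gs[j], route=route) for i, j in pairs]
    adj = bonferroni_adjust([r.p_value for r in raw], m=len(pairs))
    posthoc = []
    for (i, j), r, p_adj in zip(pairs, raw, adj):
        r.p_adjusted = p_adj
        posthoc.append((i, j, r))
    return omnibus, posthoc


def bonferroni_adjust(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p), order preserving."""
    p = [float(x) for x in p_values]
    if any(not (0.0 <= x <= 1.0) for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("family size m must be >= number of p-values")
    return [min(1.0, m * x) for x in p]
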