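"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, hand-coded formulas,
double loops) and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math


def mann_whitney_exact_p(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by full enumeration of group assignments.

    Returns (U of x, p).  Valid only for tie-free samples.
    """
    n, m = len(x), len(y)
    combined = sorted(list(x) + list(y))
    rank_of = {v: i + 1 for i, v in enumerate(combined)}

    def u_of(idx_set):
        r = sum(rank_of[combined[i - 1]] for i in idx_set)
        return r - n * (n + 1) / 2

    obs_ranks = sum(rank_of[v] for v in x)
    u_obs = obs_ranks - n * (n + 1) / 2
    total = 0
    n_le = 0
    n_ge = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        u = u_of(combo)
        total += 1
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return u_obs, p


def interpolated_quartiles(values) -> tuple[float, float]:
    """Sample quartiles by linear interpolation between order statistics."""

    def quantile(q):
        s = sorted(values)
        h = (len(s) - 1) * q
        lo = math.floor(h)
        hi = math.ceil(h)
        return s[lo] + (h - lo) * (s[hi] - s[lo])

    return quantile(0.25), quantile(0.75)


def tukey_filter_naive(values) -> tuple[list, list]:
    q1, q3 = interpolated_quartiles(values)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    kept = [v for v in values if not (v < lo or v > hi)]
    removed = [v for v in values if v < lo or v > hi]
    return kept, removed


def ols_slope(ts, ys) -> float:
    """Closed-form OLS slope sum((t-tbar)(y-ybar)) / sum((t-tbar)^2)."""
    tbar = sum(ts) / len(ts)
    ybar = sum(ys) / len(ys)
    num = sum((t - tbar) * (y - ybar) for t, y in zip(ts, ys))
    den = sum((t - tbar) ** 2 for t in ts)
    return num / den


def longest_monotone_span(times, values) -> float:
    """Longest time span of any contiguous weakly increasing run (enumeration)."""
    best = 0.0
    npts = len(values)
    for i in range(npts):
        for j in range(i, npts):
            if all(values[k + 1] >= values[k] for k in range(i, j)):
                best = max(best, times[j] - times[i])
    return best


def partition_naive(treatment: dict, genotype: dict) -> dict[str, set]:
    """Per-gene sign rule applied with an explicit double loop.

    Inputs map gene_id -> signed fold change (already thresholded).
    """
    out = {"corrected_down": set(), "corrected_up": set(), "worsened": set(), "novel": set()}
    for gene, t_fc in treatment.items():
        found = False
        for g_gene, g_fc in genotype.items():
            if g_gene == gene:
                found = True
                if (t_fc > 0) != (g_fc > 0):
                    out["corrected_down" if t_fc < 0 else "corrected_up"].add(gene)
                else:
                    out["worsened"].add(gene)
                break
        if not found:
            out["novel"].add(gene)
    return out
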