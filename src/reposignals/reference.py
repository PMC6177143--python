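"""Deliberately naive reference implementations.

Each function here recomputes a quantity by direct enumeration or by a
definition-level formulation (exact rational arithmetic, tail sums,
root-finding on the binomial CDF), independently of the vectorized
production code paths.  They are slow by design and exist so the fast
paths can be validated against them on small instances.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

from scipy import optimize, stats


def brute_force_nsr(d: Sequence[int], o: Sequence[int],
                    window: int) -> tuple[int, int]:
    """Null-effect SR numerator/denominator by enumerating every
    (drug-month, diagnosis-month) pair within the window."""
    n_after = 0
    n_before = 0
    m_total = len(d)
    for m in range(m_total):
        for k in range(m_total):
            if 0 < k - m <= window:
                n_after += d[m] * o[k]
            elif 0 < m - k <= window:
                n_before += d[m] * o[k]
    return n_after, n_before


def brute_force_pairs(drug_months: dict[str, int], dx_months: dict[str, int],
                      window: int) -> tuple[int, int, int]:
    """(n_after, n_before, n_same_month) by per-patient enumeration."""
    n_after = n_before = n_same = 0
    for patient, m_drug in drug_months.items():
        if patient not in dx_months:
            continue
        gap = dx_months[patient] - m_drug
        if gap == 0:
            n_same += 1
        elif 0 < gap <= window:
            n_after += 1
        elif 0 < -gap <= window:
            n_before += 1
    return n_after, n_before, n_same


def exact_odds_ratio(a: int, b: int, c: int, d: int) -> Fraction:
    """Odds ratio by exact cross-multiplication (rational arithmetic)."""
    if b * c == 0:
        raise ZeroDivisionError("zero cell in denominator")
    return Fraction(a * d, b * c)


def clopper_pearson_by_inversion(k: int, n: int, alpha: float = 0.05,
                                 ) -> tuple[float, float]:
    """Exact binomial CI by root-finding on the binomial tail.

    The lower bound solves ``P(X >= k | p) = alpha/2`` and the upper
    bound ``P(X <= k | p) = alpha/2`` — the defining equations, solved
    numerically rather than through beta quantiles.
    """
    half = alpha / 2
    if k == 0:
        low = 0.0
    else:
        low = optimize.brentq(
            lambda p: stats.binom.sf(k - 1, n, p) - half, 1e-12, 1 - 1e-12,
            xtol=1e-14)
    if k == n:
        high = 1.0
    else:
        high = optimize.brentq(
            lambda p: stats.binom.cdf(k, n, p) - half, 1e-12, 1 - 1e-12,
            xtol=1e-14)
    return low, high


def hypergeom_tail_by_enumeration(k: int, universe: int, set1: int,
                                  set2: int) -> float:
    """P(overlap >= k) as an explicit sum of hypergeometric point masses
    computed from binomial coefficients (exact rationals, then float)."""
    from math import comb

    total = comb(universe, set2)
    acc = Fraction(0)
    for j in range(k, min(set1, set2) + 1):
        acc += Fraction(comb(set1, j) * comb(universe - set1, set2 - j),
                        total)
    return float(acc)


def brute_force_connectivity(query_up: Sequence[str],
                             query_down: Sequence[str],
                             reference: Sequence[str]) -> float:
    """Raw connectivity score via direct evaluation of the running-max
    formulas with plain Python loops."""
    n = len(reference)
    rank = {g: i + 1 for i, g in enumerate(reference)}

    def ks(tags: Sequence[str]) -> float:
        v = sorted(rank[g] for g in tags)
        t = len(v)
        a = max(j / t - v[j - 1] / n for j in range(1, t + 1))
        b = max(v[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
        return a if a > b else -b

    ks_up = ks(query_up)
    ks_down = ks(query_down)
    if ks_up * ks_down > 0:
        return 0.0
    return ks_up - ks_down
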