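"""Disproportionality statistics: reporting odds ratio and BCPNN IC.

Both statistics read a case/noncase 2x2 table of drug-reaction pairs.
The reporting odds ratio ``ROR = ad/bc`` carries a Wald interval on the
log scale (Woolf variance ``1/a + 1/b + 1/c + 1/d``), with Haldane's
+0.5 continuity correction applied to all four cells when any cell is
zero.  The information component ``IC = log2 O/E`` is Bayesian: the
default is the closed-form BCPNN posterior moments (Bate et al.'s 1998
formulation with Beta(1,1)-margin / shrunk-joint priors), an
alternative is the modern gamma-smoothed variant ``log2((a+0.5)/(E+0.5))``
with a gamma-posterior credible interval.  A pair is an *inverse
signal* when the ROR's 95% upper bound is below 1 AND the IC's 95%
upper bound is below 0; a *risk signal* mirrors that above the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .faers import ContingencyTable, PairTable, contingency
from .types import SignalClass

IC_METHODS = ("bcpnn-1998", "gamma-smoothed")


@dataclass
class EstimateWithCI:
    """Point estimate with two-sided interval.

    ``scale`` is ``ratio`` (ROR) or ``log2`` (IC).  ``corrected`` marks
    Haldane-adjusted ROR tables; ``defined`` is False when margins are
    degenerate.
    """

    estimate: float
    ci_low: float
    ci_high: float
    scale: str
    alpha: float
    method: str | None = None
    corrected: bool = False
    defined: bool = True


def ror(table: ContingencyTable, alpha: float = 0.05) -> EstimateWithCI:
    """Reporting odds ratio with Woolf log-scale CI.

    Any zero cell triggers Haldane's +0.5 on all four cells (flagged).
    A zero margin (drug or condition absent from one side entirely)
    leaves the ratio undefined.
    """
    if table.n < 1:
        raise ValueError("empty contingency table")
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return EstimateWithCI(float("nan"), float("nan"), float("nan"),
                              scale="ratio", alpha=alpha, defined=False)
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    estimate = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EstimateWithCI(
        estimate=estimate,
        ci_low=estimate * math.exp(-z * se),
        ci_high=estimate * math.exp(z * se),
        scale="ratio", alpha=alpha, corrected=corrected)


def _ic_bcpnn_1998(a: int, n_drug: int, n_event: int, n: int,
                   alpha: float) -> tuple[float, float, float]:
    """Closed-form BCPNN posterior mean and variance of the IC.

    Priors: alpha1 = beta1 = 1 on the margins, alpha = beta = 2 on
    their totals, gamma11 = 1 on the joint cell with gamma tuned so the
    prior IC is centred at zero.
    """
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    g = g11 * (n + al) * (n + be) / ((n_drug + a1) * (n_event + b1))
    e_ic = math.log2(
        (a + g11) * (n + al) * (n + be)
        / ((n + g) * (n_drug + a1) * (n_event + b1)))
    v_ic = (1 / math.log(2)) ** 2 * (
        (n - a + g - g11) / ((a + g11) * (1 + n + g))
        + (n - n_drug + al - a1) / ((n_drug + a1) * (1 + n + al))
        + (n - n_event + be - b1) / ((n_event + b1) * (1 + n + be)))
    z = float(stats.norm.ppf(1 - alpha / 2))
    half = z * math.sqrt(v_ic)
    return e_ic, e_ic - half, e_ic + half


def _ic_gamma(a: int, n_drug: int, n_event: int, n: int,
              alpha: float) -> tuple[float, float, float]:
    """Gamma-smoothed IC with gamma-posterior credible interval."""
    e = n_drug * n_event / n
    est = math.log2((a + 0.5) / (e + 0.5))
    lo_q, hi_q = stats.gamma.ppf([alpha / 2, 1 - alpha / 2], a + 0.5)
    return est, math.log2(lo_q / (e + 0.5)), math.log2(hi_q / (e + 0.5))


def ic(table: ContingencyTable, alpha: float = 0.05,
       method: str = "bcpnn-1998") -> EstimateWithCI:
    """Bayesian information component ``log2 O/E`` with interval.

    Shrinkage is built into both variants, so zero cells need no
    continuity correction; zero margins leave the IC undefined.
    """
    if method not in IC_METHODS:
        raise ValueError(f"unknown IC method {method!r}")
    n = table.n
    if n < 1:
        raise ValueError("empty contingency table")
    n_drug = table.a + table.b
    n_event = table.a + table.c
    if n_drug == 0 or n_event == 0:
        return EstimateWithCI(float("nan"), float("nan"), float("nan"),
                              scale="log2", alpha=alpha, method=method,
                              defined=False)
    fn = _ic_bcpnn_1998 if method == "bcpnn-1998" else _ic_gamma
    est, lo, hi = fn(table.a, n_drug, n_event, n, alpha)
    return EstimateWithCI(estimate=est, ci_low=lo, ci_high=hi,
                          scale="log2", alpha=alpha, method=method)


def classify_dpa(ror_result: EstimateWithCI,
                 ic_result: EstimateWithCI) -> SignalClass:
    """Joint ROR + IC classification: both indices must agree.

    Inverse iff ROR upper bound < 1 and IC upper bound < 0; risk iff
    both lower bounds exceed their nulls; undefined inputs propagate.
    """
    if not (ror_result.defined and ic_result.defined):
        return SignalClass.UNDEFINED
    if ror_result.ci_high < 1 and ic_result.ci_high < 0:
        return SignalClass.INVERSE
    if ror_result.ci_low > 1 and ic_result.ci_low > 0:
        return SignalClass.RISK
    return SignalClass.NONE


def run_dpa(pair_table: PairTable, drug_codes: Sequence[str],
            conditions: Sequence[str], alpha: float = 0.05,
            ic_method: str = "bcpnn-1998",
            ) -> tuple[pd.DataFrame, dict[tuple[str, str], SignalClass]]:
    """ROR + IC sweep over every drug x condition pair.

    Returns the tidy estimate table (one row per pair, IC method
    stamped on every row) and the per-pair classification.
    """
    rows = []
    classes: dict[tuple[str, str], SignalClass] = {}
    for drug in drug_codes:
        for cond in conditions:
            tab = contingency(pair_table, drug, cond)
            r = ror(tab, alpha)
            i = ic(tab, alpha, ic_method)
            cls = classify_dpa(r, i)
            classes[(drug, cond)] = cls
            rows.append({
                "drug": drug, "disease": cond,
                "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
                "ror": r.estimate, "ror_low": r.ci_low, "ror_high": r.ci_high,
                "ror_corrected": r.corrected,
                "ic": i.estimate, "ic_low": i.ci_low, "ic_high": i.ci_high,
                "ic_method": ic_method, "class": cls.value,
            })
    return pd.DataFrame(rows), classes
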