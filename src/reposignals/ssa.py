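"""Sequence symmetry analysis with Halls' trend correction.

SSA compares how often an outcome is first diagnosed *after* versus
*before* initiation of a drug within a window of ``w`` months.  The
crude sequence ratio ``SR = n_after / n_before`` is biased by secular
trends in either event stream, so it is divided by the null-effect SR —
the SR expected under independence given the observed monthly incident
counts of both events, restricted to the same window — yielding the
adjusted sequence ratio (ASR).  ASR < 1 indicates an inverse
association.  Confidence limits come from the exact (Clopper–Pearson)
binomial interval for ``n_after`` out of ``n_after + n_before``,
transformed to the odds scale and divided by the null-effect SR.

A drug-disease pair is classified an *inverse signal* when the ASR's
95% interval lies entirely below 1 in at least ``min_windows`` of the
analysis windows (default: 3 of the 6/12/24/36-month windows), and a
*risk signal* symmetrically above 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .claims import apply_run_in, first_events, monthly_counts
from .types import SignalClass

DEFAULT_WINDOWS = (6, 12, 24, 36)


@dataclass(frozen=True)
class PairCounts:
    """Ordered drug/diagnosis pair counts within one window.

    ``n_same_month`` pairs (order unobservable at monthly resolution)
    are excluded from the analyzed total ``n = n_after + n_before`` but
    reported.
    """

    n_after: int
    n_before: int
    n_same_month: int
    window: int

    @property
    def n(self) -> int:
        return self.n_after + self.n_before


@dataclass
class SsaResult:
    """One drug-disease-window SSA estimate with exact CI."""

    drug: str
    disease: str
    window: int
    n_after: int
    n_before: int
    n_same_month: int
    crude_sr: float
    null_sr: float
    asr: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    @property
    def defined(self) -> bool:
        return math.isfinite(self.asr)


def build_pairs(incident_drug: pd.DataFrame, incident_dx: pd.DataFrame,
                window: int) -> PairCounts:
    """Count diagnosis-after vs diagnosis-before pairs within ``window``.

    Both inputs are per-patient incident tables (``patient_id, month``).
    Only patients present in both streams with ``0 < |m_dx - m_drug| <=
    window`` contribute; same-month pairs are counted separately and
    excluded.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    merged = incident_drug.merge(incident_dx, on="patient_id",
                                 suffixes=("_drug", "_dx"))
    gap = merged["month_dx"].to_numpy() - merged["month_drug"].to_numpy()
    inside = np.abs(gap) <= window
    return PairCounts(
        n_after=int(np.sum(inside & (gap > 0))),
        n_before=int(np.sum(inside & (gap < 0))),
        n_same_month=int(np.sum(gap == 0)),
        window=window,
    )


def crude_sr(pair_counts: PairCounts) -> float:
    """Crude sequence ratio ``n_after / n_before``; NaN when undefined."""
    if pair_counts.n_before == 0:
        return float("nan")
    return pair_counts.n_after / pair_counts.n_before


def null_effect_counts(d: np.ndarray, o: np.ndarray,
                       window: int) -> tuple[int, int]:
    """Integer numerator/denominator of the windowed null-effect SR.

    ``A`` sums, over every drug-initiation month ``m``, the outcome
    counts in ``(m, m+window]``; ``B`` the counts in ``[m-window, m)``.
    ``A/B`` is the probability ratio P(diagnosis after)/P(diagnosis
    before) over independent event-month pairs within the window —
    Halls' expected SR under no association, truncated to the same
    window and study period as the observed pairs.
    """
    d = np.asarray(d, dtype=np.int64)
    o = np.asarray(o, dtype=np.int64)
    if d.shape != o.shape:
        raise ValueError("monthly count vectors differ in length")
    m_total = len(d)
    cum = np.concatenate([[0], np.cumsum(o)])  # cum[k] = sum o[0:k]
    months = np.arange(m_total)
    hi = np.minimum(months + window, m_total - 1)
    after = cum[hi + 1] - cum[months + 1]
    lo = np.maximum(months - window, 0)
    before = cum[months] - cum[lo]
    a = int(np.dot(d, after))
    b = int(np.dot(d, before))
    return a, b


def null_effect_sr(d: np.ndarray, o: np.ndarray, window: int) -> float:
    """Null-effect SR (Halls); NaN when the denominator is zero."""
    if np.sum(d) <= 0 or np.sum(o) <= 0:
        raise ValueError("both event streams must have events")
    a, b = null_effect_counts(d, o, window)
    if b == 0:
        return float("nan")
    return a / b


def clopper_pearson(k: int, n: int, alpha: float = 0.05,
                    ) -> tuple[float, float]:
    """Exact binomial CI for a proportion, via beta quantiles."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(
        stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def asr_with_ci(pair_counts: PairCounts, null_sr: float,
                alpha: float = 0.05, drug: str = "", disease: str = "",
                ) -> SsaResult:
    """Adjusted sequence ratio with exact binomial CI.

    ``n_after`` is treated as Binomial(n, p); the Clopper–Pearson
    bounds on p are mapped to the sequence-ratio scale via the odds
    transform ``p/(1-p)`` and divided by the null-effect SR.  A zero
    ``n_before`` yields an infinite (flagged) ASR; ``n_after = n``
    yields an infinite upper bound.
    """
    n = pair_counts.n
    csr = crude_sr(pair_counts)
    base = dict(drug=drug, disease=disease, window=pair_counts.window,
                n_after=pair_counts.n_after, n_before=pair_counts.n_before,
                n_same_month=pair_counts.n_same_month, alpha=alpha)
    if n == 0 or not math.isfinite(null_sr) or null_sr <= 0:
        return SsaResult(crude_sr=csr, null_sr=null_sr, asr=float("nan"),
                         ci_low=float("nan"), ci_high=float("nan"), **base)
    p_low, p_high = clopper_pearson(pair_counts.n_after, n, alpha)
    ci_low = (p_low / (1 - p_low)) / null_sr
    ci_high = float("inf") if p_high == 1 else (p_high / (1 - p_high)) / null_sr
    asr = (float("inf") if pair_counts.n_before == 0
           else csr / null_sr)
    return SsaResult(crude_sr=csr, null_sr=null_sr, asr=asr,
                     ci_low=ci_low, ci_high=ci_high, **base)


def classify_ssa(results: Iterable[SsaResult],
                 min_windows: int = 3) -> SignalClass:
    """Classify a drug-disease pair from its per-window ASR intervals.

    Inverse iff the CI upper bound is below 1 in at least
    ``min_windows`` windows; risk iff the lower bound exceeds 1 in at
    least ``min_windows``; undefined windows count as not significant.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one window result")
    n_inverse = sum(1 for r in results
                    if math.isfinite(r.ci_high) and r.ci_high < 1)
    n_risk = sum(1 for r in results
                 if math.isfinite(r.ci_low) and r.ci_low > 1)
    if n_inverse >= min_windows:
        return SignalClass.INVERSE
    if n_risk >= min_windows:
        return SignalClass.RISK
    return SignalClass.NONE


def run_ssa(events: pd.DataFrame, enrollment: pd.DataFrame,
            drug_codes: Sequence[str], dx_codes: Sequence[str],
            study_months: int, windows: Sequence[int] = DEFAULT_WINDOWS,
            run_in_months: int = 6, alpha: float = 0.05,
            min_windows: int = 3,
            ) -> tuple[pd.DataFrame, dict[tuple[str, str], SignalClass]]:
    """Full SSA sweep over every drug x disease pair.

    For each code, first events are derived and run-in filtered; the
    null-effect SR uses the monthly incident counts of *all* incident
    events of each code (not just paired patients), matching Halls'
    marginal-trend formulation.  Returns the tidy per-window result
    table and the per-pair classification.
    """
    incidents: dict[tuple[str, str], pd.DataFrame] = {}
    for kind, codes in (("prescription", drug_codes), ("diagnosis", dx_codes)):
        for code in codes:
            fe = first_events(events, kind, {code})
            incidents[(kind, code)] = apply_run_in(
                fe, enrollment, run_in_months).events

    rows = []
    classes: dict[tuple[str, str], SignalClass] = {}
    for drug in drug_codes:
        inc_drug = incidents[("prescription", drug)]
        d_m = monthly_counts(inc_drug, study_months)
        for disease in dx_codes:
            inc_dx = incidents[("diagnosis", disease)]
            o_m = monthly_counts(inc_dx, study_months)
            per_window = []
            for w in windows:
                pc = build_pairs(inc_drug, inc_dx, w)
                if d_m.sum() == 0 or o_m.sum() == 0:
                    nsr = float("nan")
                else:
                    nsr = null_effect_sr(d_m, o_m, w)
                res = asr_with_ci(pc, nsr, alpha, drug=drug, disease=disease)
                per_window.append(res)
                rows.append(res)
            classes[(drug, disease)] = classify_ssa(per_window, min_windows)

    table = pd.DataFrame([vars(r) for r in rows])
    table["class"] = table.apply(
        lambda r: classes[(r["drug"], r["disease"])].value, axis=1)
    return table, classes
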