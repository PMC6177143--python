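"""Spontaneous-report ingestion and drug-reaction pair counting.

Reports arrive in a FAERS-like relational layout: DEMO rows link a
report identifier to a case number, DRUG rows carry raw drug-name
strings, REAC rows carry event terms.  The store deduplicates reports
by case number (keeping the latest report version), maps raw drug names
and event terms through user-supplied dictionaries, expands each report
into its drug x reaction pairs (deduplicated within report), and builds
the case/noncase 2x2 table for any (drug, condition) query at pair
granularity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

UNMAPPED_PREFIX = "unmapped:"


@dataclass
class ReportSet:
    """Linked DEMO/DRUG/REAC tables plus orphan-row tallies."""

    demo: pd.DataFrame       # report_id, case_id
    drugs: pd.DataFrame      # report_id, drugname
    reactions: pd.DataFrame  # report_id, pt
    n_orphan_drugs: int = 0
    n_orphan_reactions: int = 0

    @property
    def n_reports(self) -> int:
        return len(self.demo)


@dataclass
class PairTable:
    """Mapped drug-reaction pairs; ``n_pairs`` is the DPA denominator."""

    pairs: pd.DataFrame  # report_id, drug_code, event_condition
    n_pairs: int


@dataclass(frozen=True)
class ContingencyTable:
    """Case/noncase 2x2 pair counts for one (drug, condition) query.

    ``a``: target drug & target condition; ``b``: target drug, other
    condition; ``c``: other drug, target condition; ``d``: neither.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def read_reports(demo_path: str | Path, drug_path: str | Path,
                 reaction_path: str | Path) -> ReportSet:
    """Read and link the three report tables.

    Drug or reaction rows whose ``report_id`` has no DEMO row are
    excluded and tallied (FAERS quarters contain such orphans).
    """
    demo = pd.read_csv(demo_path, sep=None, engine="python", dtype=str)
    drugs = pd.read_csv(drug_path, sep=None, engine="python", dtype=str)
    reac = pd.read_csv(reaction_path, sep=None, engine="python", dtype=str)
    for name, df, cols in (("DEMO", demo, {"report_id", "case_id"}),
                           ("DRUG", drugs, {"report_id", "drugname"}),
                           ("REAC", reac, {"report_id", "pt"})):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{name} file missing columns {sorted(missing)}")
    known = set(demo["report_id"])
    drug_ok = drugs["report_id"].isin(known)
    reac_ok = reac["report_id"].isin(known)
    n_orphan_drugs = int((~drug_ok).sum())
    n_orphan_reactions = int((~reac_ok).sum())
    if n_orphan_drugs or n_orphan_reactions:
        logger.warning("excluded %d orphan drug rows, %d orphan reaction rows",
                       n_orphan_drugs, n_orphan_reactions)
    return ReportSet(demo=demo.reset_index(drop=True),
                     drugs=drugs[drug_ok].reset_index(drop=True),
                     reactions=reac[reac_ok].reset_index(drop=True),
                     n_orphan_drugs=n_orphan_drugs,
                     n_orphan_reactions=n_orphan_reactions)


def _version_key(report_ids: pd.Series) -> pd.Series:
    """Sort key treating numeric report ids numerically, others textually."""
    nums = pd.to_numeric(report_ids, errors="coerce")
    if nums.notna().all():
        return nums
    return report_ids


def deduplicate(reports: ReportSet) -> ReportSet:
    """Keep exactly one report per case: the greatest report_id.

    Case numbers identify the patient episode; several report versions
    may share one case.  The retained version is the
    numerically/lexicographically greatest report_id (latest).
    Idempotent and order-independent.
    """
    demo = reports.demo.assign(_key=_version_key(reports.demo["report_id"]))
    demo = (demo.sort_values(["case_id", "_key", "report_id"], kind="mergesort")
            .drop_duplicates("case_id", keep="last")
            .drop(columns="_key")
            .sort_values("report_id", kind="mergesort")
            .reset_index(drop=True))
    keep = set(demo["report_id"])
    return ReportSet(
        demo=demo,
        drugs=reports.drugs[reports.drugs["report_id"].isin(keep)]
        .reset_index(drop=True),
        reactions=reports.reactions[reports.reactions["report_id"].isin(keep)]
        .reset_index(drop=True),
        n_orphan_drugs=reports.n_orphan_drugs,
        n_orphan_reactions=reports.n_orphan_reactions,
    )


def _normalize(term: str) -> str:
    return re.sub(r"\s+", " ", str(term).strip().lower())


def read_dictionary(path: str | Path) -> dict[str, str]:
    """Two-column TSV (raw_term, code) -> normalized lookup dict."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: dictionary needs two columns")
    raw, code = df.columns[:2]
    return {_normalize(t): c for t, c in zip(df[raw], df[code])}


def map_terms(terms: pd.Series, dictionary: Mapping[str, str]) -> pd.Series:
    """Case-insensitive, whitespace-normalized lookup; unmapped terms
    pass through in a reserved ``unmapped:`` namespace (no fuzzy
    matching, so behavior stays auditable)."""
    normalized = terms.map(_normalize)
    return normalized.map(
        lambda t: dictionary.get(t, UNMAPPED_PREFIX + t))


def build_pair_table(reports: ReportSet, drug_dict: Mapping[str, str],
                     event_dict: Mapping[str, str]) -> PairTable:
    """Expand reports to mapped drug x reaction pairs.

    The cross-product is taken per report and deduplicated within
    report per (drug_code, event_condition) — a drug listed twice does
    not double-count its pairs.
    """
    drugs = reports.drugs.assign(
        drug_code=map_terms(reports.drugs["drugname"], drug_dict))
    reac = reports.reactions.assign(
        event_condition=map_terms(reports.reactions["pt"], event_dict))
    pairs = (drugs[["report_id", "drug_code"]]
             .merge(reac[["report_id", "event_condition"]], on="report_id")
             .drop_duplicates()
             .sort_values(["report_id", "drug_code", "event_condition"],
                          kind="mergesort")
             .reset_index(drop=True))
    return PairTable(pairs=pairs, n_pairs=len(pairs))


def contingency(pair_table: PairTable, drug_code: str,
                condition: str) -> ContingencyTable:
    """Case/noncase 2x2 at pair granularity; a+b+c+d = n_pairs."""
    if pair_table.n_pairs < 1:
        raise ValueError("empty pair table")
    p = pair_table.pairs
    is_drug = (p["drug_code"] == drug_code).to_numpy()
    is_cond = (p["event_condition"] == condition).to_numpy()
    a = int((is_drug & is_cond).sum())
    b = int((is_drug & ~is_cond).sum())
    c = int((~is_drug & is_cond).sum())
    d = int((~is_drug & ~is_cond).sum())
    return ContingencyTable(a=a, b=b, c=c, d=d)


def report_based_contingency(reports: ReportSet,
                             drug_dict: Mapping[str, str],
                             event_dict: Mapping[str, str],
                             drug_code: str, condition: str,
                             ) -> ContingencyTable:
    """Report-granularity 2x2 (sensitivity-analysis alternative).

    Cases are reports mentioning the condition; exposure is any mention
    of the drug.  Provided alongside the default pair-based counting.
    """
    drugs = set(reports.drugs.loc[
        map_terms(reports.drugs["drugname"], drug_dict) == drug_code,
        "report_id"])
    cases = set(reports.reactions.loc[
        map_terms(reports.reactions["pt"], event_dict) == condition,
        "report_id"])
    all_ids = set(reports.demo["report_id"])
    a = len(drugs & cases)
    b = len(drugs - cases)
    c = len(cases - drugs)
    d = len(all_ids) - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)
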