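"""Longitudinal claims ingestion and incident-event derivation.

Claims arrive as monthly event rows (prescription or diagnosis per
patient per month); time is an integer month index, 0-based from study
start, over a half-open study period ``[0, M)``.  The module reads and
validates the delimited files, derives per-patient first events,
applies the incident-user run-in rule (a first event inside the run-in
marks the patient as prevalent and removes them for that code — they
are excluded, not shifted), and emits a waiting-time histogram used to
check that the incident restriction worked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["patient_id", "month", "kind", "code"]
KINDS = ("prescription", "diagnosis")


@dataclass
class LoadSummary:
    """Audit counts from one :func:`read_claims` call."""

    n_rows: dict = field(default_factory=dict)
    n_out_of_range: dict = field(default_factory=dict)

    def total_rejected(self) -> int:
        return sum(self.n_out_of_range.values())


def _read_event_file(path: str | Path, kind: str, code_col: str,
                     study_months: int, summary: LoadSummary) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"patient_id", "month", code_col}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    months = pd.to_numeric(df["month"], errors="coerce")
    bad = months.isna() | (months != months.round())
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise ValueError(f"{path}:{line}: non-integer month "
                         f"{df['month'].iloc[line - 2]!r}")
    empty = df["patient_id"].isna() | (df["patient_id"].str.strip() == "") \
        | df[code_col].isna() | (df[code_col].str.strip() == "")
    if empty.any():
        line = int(np.flatnonzero(empty.to_numpy())[0]) + 2
        raise ValueError(f"{path}:{line}: empty patient_id or code")
    out = pd.DataFrame({
        "patient_id": df["patient_id"],
        "month": months.astype(int),
        "kind": kind,
        "code": df[code_col],
    })
    in_range = (out["month"] >= 0) & (out["month"] < study_months)
    summary.n_rows[path.name] = len(out)
    summary.n_out_of_range[path.name] = int((~in_range).sum())
    if summary.n_out_of_range[path.name]:
        logger.warning("%s: rejected %d rows outside [0, %d)",
                       path.name, summary.n_out_of_range[path.name],
                       study_months)
    return out[in_range]


def read_claims(prescriptions_path: str | Path, diagnoses_path: str | Path,
                enrollment_path: str | Path | None, study_months: int,
                ) -> tuple[pd.DataFrame, pd.DataFrame, LoadSummary]:
    """Read prescription, diagnosis, and enrollment tables.

    Returns ``(events, enrollment, summary)``.  ``events`` has columns
    ``patient_id, month, kind, code`` sorted deterministically; rows
    with months outside ``[0, study_months)`` are dropped and counted
    in the summary.  Malformed rows raise with file and line number.
    """
    summary = LoadSummary()
    rx = _read_event_file(prescriptions_path, "prescription", "drug_code",
                          study_months, summary)
    dx = _read_event_file(diagnoses_path, "diagnosis", "condition_code",
                          study_months, summary)
    events = pd.concat([rx, dx], ignore_index=True)
    events = events.sort_values(EVENT_COLUMNS, kind="mergesort",
                                ignore_index=True)

    if enrollment_path is None:
        enrollment = pd.DataFrame(columns=["patient_id", "enroll_month",
                                           "disenroll_month"])
    else:
        enrollment = pd.read_csv(enrollment_path, sep=None, engine="python",
                                 dtype={"patient_id": str})
        need = {"patient_id", "enroll_month"}
        if need - set(enrollment.columns):
            raise ValueError(f"{enrollment_path}: missing columns "
                             f"{sorted(need - set(enrollment.columns))}")
        # enrollment may precede study start; floor at 0
        enrollment["enroll_month"] = (
            pd.to_numeric(enrollment["enroll_month"]).astype(int).clip(lower=0)
        )
        if "disenroll_month" not in enrollment.columns:
            enrollment["disenroll_month"] = pd.NA
        enrollment = enrollment.sort_values("patient_id", ignore_index=True)
    return events, enrollment, summary


def write_claims(events: pd.DataFrame, prescriptions_path: str | Path,
                 diagnoses_path: str | Path) -> None:
    """Serialize an event table back to the two-file on-disk layout."""
    rx = events[events["kind"] == "prescription"]
    dx = events[events["kind"] == "diagnosis"]
    rx.rename(columns={"code": "drug_code"})[
        ["patient_id", "month", "drug_code"]
    ].to_csv(prescriptions_path, sep="\t", index=False)
    dx.rename(columns={"code": "condition_code"})[
        ["patient_id", "month", "condition_code"]
    ].to_csv(diagnoses_path, sep="\t", index=False)


def first_events(events: pd.DataFrame, kind: str,
                 code_set: Iterable[str]) -> pd.DataFrame:
    """Per-patient first occurrence of any event of ``kind`` in ``code_set``.

    One row per patient with at least one matching event; ``month`` is
    the minimum matching month.  Applied to its own output (as a
    single-code event table) the operation is idempotent.
    """
    codes = set(code_set)
    if not codes:
        raise ValueError("code_set must be non-empty")
    if kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}")
    m = events[(events["kind"] == kind) & events["code"].isin(codes)]
    out = (m.groupby("patient_id", as_index=False)["month"].min()
           .sort_values("patient_id", ignore_index=True))
    return out


@dataclass
class IncidentTable:
    """Run-in-filtered first events plus audit counts."""

    events: pd.DataFrame          # patient_id, month
    n_prevalent_excluded: int
    n_missing_enrollment: int


def apply_run_in(first: pd.DataFrame, enrollment: pd.DataFrame,
                 run_in_months: int = 6,
                 missing_enrollment: str = "study-start") -> IncidentTable:
    """Keep first events at or after ``enroll_month + run_in_months``.

    A first event inside the run-in identifies a prevalent user, who is
    excluded entirely (not shifted to a later event).  Patients without
    an enrollment record are treated as enrolled at study start under
    the default policy (counted and logged); ``missing_enrollment=
    "error"`` raises instead.
    """
    if run_in_months < 0:
        raise ValueError("run_in_months must be >= 0")
    merged = first.merge(
        enrollment[["patient_id", "enroll_month"]], on="patient_id",
        how="left")
    n_missing = int(merged["enroll_month"].isna().sum())
    if n_missing and missing_enrollment == "error":
        raise ValueError(f"{n_missing} patients lack enrollment records")
    if n_missing:
        logger.warning("%d patients missing enrollment; treated as enrolled "
                       "at study start", n_missing)
    enroll = (pd.to_numeric(merged["enroll_month"], errors="coerce")
              .fillna(0).astype(int).clip(lower=0))
    keep = merged["month"] >= enroll + run_in_months
    out = merged.loc[keep, ["patient_id", "month"]].reset_index(drop=True)
    return IncidentTable(events=out,
                         n_prevalent_excluded=int((~keep).sum()),
                         n_missing_enrollment=n_missing)


@dataclass
class WaitingTimeCurve:
    """Monthly histogram of first events for incident-user diagnostics.

    ``ratio`` compares mean monthly mass inside the first
    ``run_in_months`` months with mean mass afterwards; a flat curve
    gives about 1, an early spike (prevalent-user contamination) gives
    a large value.  No automated pass/fail — the curve is for
    inspection.
    """

    code: str
    counts: np.ndarray
    run_in_months: int
    ratio: float
    flagged: bool


def waiting_time(first: pd.DataFrame, study_months: int,
                 run_in_months: int = 6, code: str = "") -> WaitingTimeCurve:
    counts = np.bincount(first["month"].to_numpy(),
                         minlength=study_months)[:study_months]
    head = counts[:run_in_months]
    tail = counts[run_in_months:]
    head_mean = head.mean() if head.size else 0.0
    tail_mean = tail.mean() if tail.size else 0.0
    if tail_mean == 0:
        ratio = float("inf") if head_mean > 0 else 1.0
        flagged = head_mean > 0
    else:
        ratio = float(head_mean / tail_mean)
        flagged = False
    return WaitingTimeCurve(code=code, counts=counts,
                            run_in_months=run_in_months, ratio=ratio,
                            flagged=flagged)


def monthly_counts(incident: pd.DataFrame, study_months: int) -> np.ndarray:
    """Histogram of incident events per month (length ``study_months``)."""
    return np.bincount(incident["month"].to_numpy(),
                       minlength=study_months)[:study_months]
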