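"""Combine SSA and DPA classifications into the repositioning matrix.

A drug-disease pair is a *drug-repositioning signal* only when both
evidence streams independently classify it inverse; an inverse signal
from a single method is reported separately.  A pair inverse on one
method but risk on the other is contradictory evidence and classified
none with a conflict annotation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import claims, dpa, faers, ssa
from .types import CombinedClass, SignalClass

logger = logging.getLogger(__name__)


def combine_classes(ssa_class: SignalClass,
                    dpa_class: SignalClass) -> tuple[CombinedClass, bool]:
    """Combined verdict plus a conflict flag for one pair."""
    inverse = {ssa_class, dpa_class} == {SignalClass.INVERSE}
    conflict = {ssa_class, dpa_class} == {SignalClass.INVERSE,
                                          SignalClass.RISK}
    if inverse:
        return CombinedClass.REPOSITIONING_SIGNAL, False
    if conflict:
        return CombinedClass.NONE, True
    if SignalClass.INVERSE in (ssa_class, dpa_class):
        return CombinedClass.INVERSE_ONE_METHOD, False
    if SignalClass.RISK in (ssa_class, dpa_class):
        return CombinedClass.RISK, False
    return CombinedClass.NONE, False


def integrate(ssa_classes: Mapping[tuple[str, str], SignalClass],
              dpa_classes: Mapping[tuple[str, str], SignalClass],
              ) -> pd.DataFrame:
    """Signal matrix over the union of keys from both methods.

    A pair missing from one method is treated as ``none`` on that side.
    The output is a pure, deterministically sorted function of the
    inputs: one row per (drug, disease).
    """
    keys = sorted(set(ssa_classes) | set(dpa_classes))
    rows = []
    for drug, disease in keys:
        s = ssa_classes.get((drug, disease), SignalClass.NONE)
        d = dpa_classes.get((drug, disease), SignalClass.NONE)
        combined, conflict = combine_classes(s, d)
        rows.append({"drug": drug, "disease": disease,
                     "ssa_class": s.value, "dpa_class": d.value,
                     "combined": combined.value, "conflict": conflict})
    return pd.DataFrame(
        rows, columns=["drug", "disease", "ssa_class", "dpa_class",
                       "combined", "conflict"])


def render_signal_table(matrix: pd.DataFrame,
                        ssa_results: pd.DataFrame | None,
                        dpa_results: pd.DataFrame | None,
                        out_dir: str | Path) -> dict[str, Path]:
    """Write the symbol summary and the detailed numeric tables.

    The summary uses the field's marks (▼ inverse / △ risk / − none)
    per method column.  Output is byte-identical across runs on
    identical inputs (sorted rows, no timestamps).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    symbol = {c.value: SignalClass(c.value).symbol for c in SignalClass}
    summary = matrix.sort_values(["disease", "drug"], ignore_index=True)
    summary = summary.assign(
        ssa=summary["ssa_class"].map(symbol),
        dpa=summary["dpa_class"].map(symbol),
    )[["drug", "disease", "ssa", "dpa", "combined", "conflict"]]
    path = out / "signal_summary.tsv"
    summary.to_csv(path, sep="\t", index=False)
    written["summary"] = path

    if ssa_results is not None:
        path = out / "ssa_results.tsv"
        (ssa_results.sort_values(["disease", "drug", "window"],
                                 ignore_index=True)
         .to_csv(path, sep="\t", index=False, float_format="%.6g"))
        written["ssa"] = path
    if dpa_results is not None:
        path = out / "dpa_results.tsv"
        (dpa_results.sort_values(["disease", "drug"], ignore_index=True)
         .to_csv(path, sep="\t", index=False, float_format="%.6g"))
        written["dpa"] = path
    return written


@dataclass
class PipelineConfig:
    """Paths and parameters for one end-to-end run."""

    claims_dir: str
    reports_dir: str
    out_dir: str
    drug_codes: list[str]
    dx_codes: list[str]
    study_months: int
    windows: tuple[int, ...] = ssa.DEFAULT_WINDOWS
    run_in_months: int = 6
    alpha: float = 0.05
    min_windows: int = 3
    ic_method: str = "bcpnn-1998"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["windows"] = tuple(raw.get("windows", ssa.DEFAULT_WINDOWS))
        return cls(**raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """claims -> SSA, reports -> DPA, integrate; write artifact directory.

    Each stage failure aborts with a stage-named diagnostic.  A run
    manifest records the config and input checksums for provenance.
    """
    claims_dir = Path(config.claims_dir)
    reports_dir = Path(config.reports_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        events, enrollment, load_summary = claims.read_claims(
            claims_dir / "prescriptions.tsv", claims_dir / "diagnoses.tsv",
            claims_dir / "enrollment.tsv", config.study_months)
        ssa_table, ssa_classes = ssa.run_ssa(
            events, enrollment, config.drug_codes, config.dx_codes,
            config.study_months, config.windows, config.run_in_months,
            config.alpha, config.min_windows)
    except Exception as exc:
        raise RuntimeError(f"SSA stage failed: {exc}") from exc

    try:
        reports = faers.read_reports(
            reports_dir / "demo.tsv", reports_dir / "drug.tsv",
            reports_dir / "reac.tsv")
        reports = faers.deduplicate(reports)
        drug_dict = faers.read_dictionary(reports_dir / "drug_dict.tsv")
        event_dict = faers.read_dictionary(reports_dir / "event_dict.tsv")
        pair_table = faers.build_pair_table(reports, drug_dict, event_dict)
        dpa_table, dpa_classes = dpa.run_dpa(
            pair_table, config.drug_codes, config.dx_codes,
            config.alpha, config.ic_method)
    except Exception as exc:
        raise RuntimeError(f"DPA stage failed: {exc}") from exc

    try:
        matrix = integrate(ssa_classes, dpa_classes)
        render_signal_table(matrix, ssa_table, dpa_table, out_dir)
    except Exception as exc:
        raise RuntimeError(f"integration stage failed: {exc}") from exc

    manifest = {
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in vars(config).items()},
        "input_checksums": {
            p.name: _checksum(p)
            for p in [*sorted(claims_dir.glob("*.tsv")),
                      *sorted(reports_dir.glob("*.tsv"))]},
        "claims_rows_rejected": load_summary.total_rejected(),
        "n_pairs": pair_table.n_pairs,
        "n_ssa_tests": len(ssa_table),
        "n_dpa_tests": len(dpa_table),
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d pairs classified", len(matrix))
    return matrix
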