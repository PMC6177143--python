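#!/usr/bin/env python
"""Disproportionality analysis of the synthetic report corpus.

Deduplicates reports by case number, maps raw drug names and event
terms through the generated dictionaries, expands reports into
drug-reaction pairs, and computes ROR (Woolf CI) and BCPNN IC for every
drug x disease pair.  Writes the estimate table and the DPA
classification to results/.
"""

from pathlib import Path

from reposignals import dpa, faers, studies

DATA = Path("data/synthetic/reports")
RESULTS = Path("results")


def main() -> None:
    reports = faers.read_reports(DATA / "demo.tsv", DATA / "drug.tsv",
                                 DATA / "reac.tsv")
    n_before = reports.n_reports
    reports = faers.deduplicate(reports)
    print(f"reports: {n_before:,} -> {reports.n_reports:,} after "
          f"case-number deduplication")

    pair_table = faers.build_pair_table(
        reports, faers.read_dictionary(DATA / "drug_dict.tsv"),
        faers.read_dictionary(DATA / "event_dict.tsv"))
    print(f"drug-reaction pairs: {pair_table.n_pairs:,}")

    table, classes = dpa.run_dpa(pair_table, studies.E2E_DRUGS,
                                 studies.E2E_DISEASES)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "dpa_results.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.6g")

    inverse = sorted(k for k, v in classes.items() if v.value == "inverse")
    print(f"wrote {len(table)} pair results to {out}")
    print(f"DPA inverse signals (ROR upper < 1 AND IC upper < 0): {inverse}")
    planted = table[table["drug"] == studies.E2E_PLANTED_DRUG]
    print(planted[["drug", "disease", "a", "b", "c", "d", "ror", "ror_low",
                   "ror_high", "ic", "ic_low", "ic_high"]]
          .to_string(index=False, float_format=lambda x: f"{x:.3f}"))


if __name__ == "__main__":
    main()
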