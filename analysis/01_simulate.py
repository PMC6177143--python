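#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Creates a 10-drug, 2-disease claims cohort (drug D03 planted with a
post-initiation diagnosis rate ratio of 0.3 for both diseases), a
matching spontaneous-report corpus (D03 planted with a per-pair
reporting OR of 0.25 against both disease terms, 5% duplicate case
versions), and an expression fixture (disease up-set partially reversed
by the drug, one planted reversal in a 50-member reference panel).

Outputs land under data/synthetic/; every directory carries a
manifest.json recording the planted truth.
"""

from pathlib import Path

from reposignals import simulate, studies

SEED = 2025
DATA = Path("data/synthetic")


def main() -> None:
    claims_cfg = studies._e2e_claims_config(
        seed=SEED, n_patients=40_000, n_months=120, rho=0.3)
    sim_claims = simulate.gen_claims(claims_cfg, DATA / "claims")
    print(f"claims: {len(sim_claims.events):,} events for "
          f"{claims_cfg.n_patients:,} patients -> {DATA / 'claims'}")
    print(f"  planted: diagnosis rate ratio 0.3 after initiation of "
          f"{studies.E2E_PLANTED_DRUG} (both diseases)")

    reports_cfg = studies._e2e_reports_config(
        seed=SEED + 1, n_reports=50_000, planted_or=0.25)
    sim_reports = simulate.gen_reports(reports_cfg, DATA / "reports")
    print(f"reports: {sim_reports.reports.n_reports:,} report rows "
          f"({sim_reports.manifest['n_duplicates']:,} duplicate case "
          f"versions) -> {DATA / 'reports'}")
    print(f"  planted: per-pair reporting OR 0.25 for "
          f"{studies.E2E_PLANTED_DRUG} x both disease terms")

    expr_cfg = simulate.SimExpressionConfig(seed=SEED + 2)
    sim_expr = simulate.gen_biosets(expr_cfg, DATA / "expression")
    print(f"expression: {expr_cfg.n_genes:,} genes, panel of "
          f"{expr_cfg.panel_size} references -> {DATA / 'expression'}")
    print(f"  planted: {len(sim_expr.manifest['drug_reversed'])} disease-up "
          f"genes reversed by the drug; reversal reference "
          f"{sim_expr.manifest['planted_reference']}")


if __name__ == "__main__":
    main()
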