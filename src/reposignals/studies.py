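"""Simulation studies that characterize the pipeline's operating
properties under planted ground truth.

Each function runs one study at its stated problem size and returns a
dict of scalar metrics.  The studies are consumed both by the test
suite and by ``scripts/acceptance.py``; they are the package's own
calibration experiments:

* trend correction — a strong secular trend in drug initiation biases
  the crude SR while the adjusted SR stays near 1 (the point of Halls'
  null-effect correction);
* rate-ratio recovery — a planted post-exposure diagnosis rate ratio
  is recovered by the ASR with near-nominal CI coverage;
* reporting-OR recovery and IC null calibration for the DPA stage;
* end-to-end sensitivity/specificity of the combined repositioning
  classifier on a multi-drug study;
* recovery of a planted signature reversal by the connectivity screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dpa, faers, signatures, simulate, ssa
from .types import SignalClass

# Cohort defaults: 50k patients over 10 years.  The initiation hazard
# keeps lifetime exposure to ~20% of the cohort — one drug reaching a
# much larger share would be unrealistic, and heavy exposure also feeds
# a true diagnosis-rate effect back into the observed outcome trend
# that the null-effect SR is estimated from.  The diagnosis hazard is
# high for any single condition (~30% lifetime) because the cohort
# emulates a comorbidity-enriched subpopulation: joint-event yield at
# this scale (~1000 analyzable pairs per window) is what makes the
# recovery studies informative.
N_PATIENTS = 50_000
N_MONTHS = 120
DRUG_HAZARD = 0.002   # monthly first-initiation hazard (flat default)
DX_HAZARD = 0.003     # monthly first-diagnosis hazard (flat default)


def _child_seed(seed: int, i: int) -> int:
    return int((seed * 100_003 + 7919 * i + 1) % (2 ** 31))


# ---------------------------------------------------------------------------
# SSA studies


def _single_pair_ssa(config: simulate.SimClaimsConfig,
                     windows=(6, 12, 24, 36), run_in: int = 6,
                     ) -> dict[int, ssa.SsaResult]:
    """Simulate one cohort and compute per-window SSA for its one pair."""
    sim = simulate.gen_claims_frames(config)
    table, _ = ssa.run_ssa(sim.events, sim.enrollment, ["DRUG"], ["DX"],
                           config.n_months, windows=windows,
                           run_in_months=run_in)
    return {int(r.window): r
            for r in (ssa.SsaResult(**{k: v for k, v in row.items()
                                       if k != "class"})
                      for row in table.to_dict("records"))}


def trend_correction_study(seed: int, n_patients: int = N_PATIENTS,
                           n_months: int = N_MONTHS, n_seeds: int = 20,
                           window: int = 36) -> dict:
    """Crude vs adjusted SR under a 5-fold rising initiation trend, no
    exposure effect.

    The drug-initiation hazard rises linearly 5-fold across the study
    while the diagnosis hazard is flat and rho = 1.  Study-period
    truncation then depletes the after-window of late (frequent)
    initiations, biasing the crude SR below 1 — most visibly at the
    longest window, which is the one measured.
    """
    drug_hazard = simulate.hazard_profile("linear", n_months,
                                          DRUG_HAZARD / 2.5,
                                          DRUG_HAZARD * 2)
    dx_hazard = simulate.hazard_profile("flat", n_months, DX_HAZARD)
    crude, adjusted = [], []
    for i in range(n_seeds):
        config = simulate.SimClaimsConfig.single(
            n_patients, n_months, drug_hazard, dx_hazard, rho=1.0,
            seed=_child_seed(seed, i))
        res = _single_pair_ssa(config)[window]
        crude.append(res.crude_sr)
        adjusted.append(res.asr)
    return {
        "window": window,
        "n_seeds": n_seeds,
        "mean_crude_sr": float(np.mean(crude)),
        "mean_asr": float(np.mean(adjusted)),
    }


def null_calibration_study(seed: int, n_patients: int = N_PATIENTS,
                           n_months: int = N_MONTHS, n_seeds: int = 20,
                           window: int = 24) -> dict:
    """ASR distribution under flat trends and rho = 1 (should center at 1)."""
    drug_hazard = simulate.hazard_profile("flat", n_months, DRUG_HAZARD)
    dx_hazard = simulate.hazard_profile("flat", n_months, DX_HAZARD)
    values = []
    for i in range(n_seeds):
        config = simulate.SimClaimsConfig.single(
            n_patients, n_months, drug_hazard, dx_hazard, rho=1.0,
            seed=_child_seed(seed, i))
        values.append(_single_pair_ssa(config)[window].asr)
    return {"window": window, "n_seeds": n_seeds,
            "mean_asr": float(np.mean(values))}


def rho_recovery_study(seed: int, rho: float = 0.5,
                       n_patients: int = N_PATIENTS,
                       n_months: int = N_MONTHS, n_seeds: int = 20,
                       window: int = 24,
                       band: tuple[float, float] = (0.42, 0.58)) -> dict:
    """Recovery of a planted diagnosis rate ratio by the ASR.

    Flat trends; the planted rho halves the diagnosis hazard after
    initiation.  Reports the fraction of replicates whose ASR falls in
    ``band`` and the fraction whose 95% CI covers rho.  Read at the
    24-month window, where the pair yield makes the interval
    informative.
    """
    drug_hazard = simulate.hazard_profile("flat", n_months, DRUG_HAZARD)
    dx_hazard = simulate.hazard_profile("flat", n_months, DX_HAZARD)
    in_band = covered = 0
    estimates = []
    for i in range(n_seeds):
        config = simulate.SimClaimsConfig.single(
            n_patients, n_months, drug_hazard, dx_hazard, rho=rho,
            seed=_child_seed(seed, i))
        res = _single_pair_ssa(config)[window]
        estimates.append(res.asr)
        in_band += band[0] <= res.asr <= band[1]
        covered += res.ci_low <= rho <= res.ci_high
    return {
        "window": window, "rho": rho, "n_seeds": n_seeds,
        "median_asr": float(np.median(estimates)),
        "frac_in_band": in_band / n_seeds,
        "ci_coverage": covered / n_seeds,
    }


# ---------------------------------------------------------------------------
# DPA studies

# Spontaneous-report corpora are sparse: any one drug appears in a few
# percent of reports, and a target condition in far fewer pairs still.
# Sparsity also keeps the pair-based 2x2 interpretable: noncase pairs
# are other-reaction pairs, so the pair-level ROR estimates the event's
# reporting *rate* ratio, which coincides with the planted odds
# multiplier only when the event is rare; and a drug present in a large
# share of reports would leak its planted effect into the comparator
# pairs of co-reported drugs.
N_REPORTS = 350_000        # ~0.6 drug-reaction pairs per report -> ~210k pairs
BACKGROUND_DRUGS = [(f"D{i:02d}", 0.03) for i in range(10)]
BACKGROUND_EVENTS = [(f"E{i:02d}", 0.02 if i == 5 else 0.10)
                     for i in range(20)]


def ror_recovery_study(seed: int, planted_or: float = 0.25,
                       n_reports: int = N_REPORTS,
                       n_seeds: int = 20) -> dict:
    """Recovery of a planted reporting odds ratio at FAERS-like scale.

    CI coverage is assessed against the generator manifest's implied
    pair-level OR (the true value of the pair-based estimand, which
    differs from the raw multiplier through co-reporting masking);
    median recovery is reported against the planted multiplier itself.
    """
    estimates = []
    covered = 0
    n_pairs = []
    implied = planted_or
    for i in range(n_seeds):
        config = simulate.SimReportsConfig(
            n_reports=n_reports, drugs=BACKGROUND_DRUGS,
            events=BACKGROUND_EVENTS,
            planted=[("D03", "E05", planted_or)],
            seed=_child_seed(seed, i))
        sim = simulate.gen_reports_frames(config)
        implied = sim.manifest["implied_pair_or"]["D03|E05"]
        pair_table = faers.build_pair_table(
            faers.deduplicate(sim.reports), sim.drug_dict, sim.event_dict)
        n_pairs.append(pair_table.n_pairs)
        tab = faers.contingency(pair_table, "D03", "E05")
        r = dpa.ror(tab)
        estimates.append(r.estimate)
        covered += r.ci_low <= implied <= r.ci_high
    return {
        "planted_or": planted_or, "implied_pair_or": implied,
        "n_seeds": n_seeds,
        "mean_n_pairs": float(np.mean(n_pairs)),
        "median_ror": float(np.median(estimates)),
        "ci_coverage": covered / n_seeds,
    }


def ic_null_coverage_study(seed: int, n_tables: int = 200,
                           n_pairs: int = 50_000,
                           method: str = "bcpnn-1998") -> dict:
    """IC interval coverage of 0 across independence tables (true IC=0)."""
    tables = simulate.gen_tables(n_tables, n_pairs, p_drug=0.05,
                                 p_event=0.05, odds_multiplier=1.0,
                                 seed=seed)
    contains = 0
    for tab in tables:
        res = dpa.ic(tab, method=method)
        contains += res.ci_low <= 0 <= res.ci_high
    return {"n_tables": n_tables, "method": method,
            "coverage": contains / n_tables}


# ---------------------------------------------------------------------------
# End-to-end study


@dataclass
class EndToEndResult:
    n_runs: int
    n_planted_detected: int        # planted drug repositioning in BOTH diseases
    n_runs_with_false_positive: int
    n_exact: int                   # detected AND no other drug flagged
    detection_rate: float
    false_positive_rate: float
    exact_rate: float


E2E_DRUGS = [f"D{i:02d}" for i in range(10)]
E2E_DISEASES = ["DXA", "DXB"]
E2E_PLANTED_DRUG = "D03"


def _e2e_claims_config(seed: int, n_patients: int,
                       n_months: int, rho: float) -> simulate.SimClaimsConfig:
    flat = simulate.hazard_profile("flat", n_months, 0.002)
    dxh = simulate.hazard_profile("flat", n_months, 0.0015)
    return simulate.SimClaimsConfig(
        n_patients=n_patients, n_months=n_months,
        drug_hazards={d: flat for d in E2E_DRUGS},
        dx_hazards={s: dxh for s in E2E_DISEASES},
        effects={(E2E_PLANTED_DRUG, s): rho for s in E2E_DISEASES},
        prevalent_fraction=0.1, stagger_fraction=0.1, max_enroll_month=24,
        seed=seed)


def _e2e_reports_config(seed: int, n_reports: int,
                        planted_or: float) -> simulate.SimReportsConfig:
    return simulate.SimReportsConfig(
        n_reports=n_reports,
        drugs=[(d, 0.08) for d in E2E_DRUGS],
        events=[(s, 0.03) for s in E2E_DISEASES]
        + [(f"E{i:02d}", 0.05) for i in range(8)],
        planted=[(E2E_PLANTED_DRUG, s, planted_or) for s in E2E_DISEASES],
        duplicate_fraction=0.05,
        seed=seed)


def end_to_end_study(seed: int, n_runs: int = 20,
                     n_patients: int = 40_000, n_months: int = N_MONTHS,
                     n_reports: int = 50_000, rho: float = 0.3,
                     planted_or: float = 0.25) -> EndToEndResult:
    """Sensitivity/specificity of the combined repositioning classifier.

    Ten drugs, two diseases, one drug planted inverse in both the
    claims stream (rho) and the report stream (reporting OR).  A run
    counts as a detection when the planted drug is classified
    ``repositioning_signal`` for both diseases; any other drug
    classified ``repositioning_signal`` for any disease is a false
    positive.
    """
    from .integrate import integrate

    n_detected = 0
    n_fp_runs = 0
    n_exact = 0
    for i in range(n_runs):
        claims_sim = simulate.gen_claims_frames(
            _e2e_claims_config(_child_seed(seed, 2 * i), n_patients,
                               n_months, rho))
        _, ssa_classes = ssa.run_ssa(
            claims_sim.events, claims_sim.enrollment, E2E_DRUGS,
            E2E_DISEASES, n_months)

        reports_sim = simulate.gen_reports_frames(
            _e2e_reports_config(_child_seed(seed, 2 * i + 1), n_reports,
                                planted_or))
        pair_table = faers.build_pair_table(
            faers.deduplicate(reports_sim.reports),
            reports_sim.drug_dict, reports_sim.event_dict)
        _, dpa_classes = dpa.run_dpa(pair_table, E2E_DRUGS, E2E_DISEASES)

        matrix = integrate(ssa_classes, dpa_classes)
        hits = matrix[matrix["combined"] == "repositioning_signal"]
        planted_hits = hits[hits["drug"] == E2E_PLANTED_DRUG]
        detected = len(planted_hits) == len(E2E_DISEASES)
        fp = bool((hits["drug"] != E2E_PLANTED_DRUG).any())
        n_detected += detected
        n_fp_runs += fp
        n_exact += detected and not fp
    return EndToEndResult(
        n_runs=n_runs, n_planted_detected=n_detected,
        n_runs_with_false_positive=n_fp_runs, n_exact=n_exact,
        detection_rate=n_detected / n_runs,
        false_positive_rate=n_fp_runs / n_runs,
        exact_rate=n_exact / n_runs)


# ---------------------------------------------------------------------------
# Published-style classifier inputs

#: Interval estimates for three psycholeptics against Crohn's disease
#: (CD) and ulcerative colitis (UC), as reported in a published
#: pharmacovigilance screen; used as literal classifier inputs.  Layout:
#: drug -> disease -> {"asr": [(window, est, lo, hi), ...],
#:                     "ror": (est, lo, hi), "ic": (est, lo, hi)}.
PUBLISHED_EXAMPLES = {
    "haloperidol": {
        "CD": {"asr": [(6, 0.18, 0.02, 0.80), (12, 0.16, 0.02, 0.71),
                       (24, 0.20, 0.04, 0.71), (36, 0.18, 0.03, 0.64)],
               "ror": (0.14, 0.07, 0.25), "ic": (-2.73, -3.60, -1.86)},
        "UC": {"asr": [(6, 0.44, 0.15, 1.12), (12, 0.34, 0.13, 0.80),
                       (24, 0.30, 0.13, 0.66), (36, 0.29, 0.13, 0.61)],
               "ror": (0.22, 0.10, 0.45), "ic": (-2.05, -3.07, -1.03)},
    },
    "diazepam": {
        "CD": {"asr": [(6, 0.39, 0.26, 0.58), (12, 0.54, 0.39, 0.74),
                       (24, 0.68, 0.51, 0.90), (36, 0.66, 0.51, 0.86)],
               "ror": (0.62, 0.51, 0.73), "ic": (-0.69, -0.94, -0.42)},
        "UC": {"asr": [(6, 0.57, 0.44, 0.73), (12, 0.67, 0.54, 0.82),
                       (24, 0.69, 0.58, 0.83), (36, 0.70, 0.59, 0.83)],
               "ror": (0.43, 0.31, 0.59), "ic": (-1.19, -1.64, -0.72)},
    },
    "hydroxyzine": {
        "CD": {"asr": [(6, 0.52, 0.36, 0.75), (12, 0.58, 0.42, 0.80),
                       (24, 0.59, 0.44, 0.78), (36, 0.61, 0.47, 0.81)],
               "ror": (0.67, 0.51, 0.85), "ic": (-0.58, -0.93, -0.21)},
        "UC": {"asr": [(6, 0.57, 0.40, 0.80), (12, 0.66, 0.50, 0.87),
                       (24, 0.69, 0.54, 0.88), (36, 0.67, 0.54, 0.84)],
               "ror": (0.54, 0.36, 0.81), "ic": (-0.85, -1.43, -0.25)},
    },
}

#: Synthetic stand-in for a null control drug whose per-window and 2x2
#: estimates were not printed: every interval straddles its null value,
#: so all three indices classify "none".
SYNTHETIC_NULL_EXAMPLE = {
    "CD": {"asr": [(6, 1.05, 0.60, 1.80), (12, 0.98, 0.62, 1.55),
                   (24, 1.02, 0.70, 1.48), (36, 0.99, 0.71, 1.38)],
           "ror": (0.95, 0.80, 1.13), "ic": (-0.05, -0.30, 0.20)},
    "UC": {"asr": [(6, 0.92, 0.51, 1.62), (12, 1.08, 0.68, 1.70),
                   (24, 1.04, 0.71, 1.52), (36, 1.01, 0.72, 1.41)],
           "ror": (1.04, 0.86, 1.26), "ic": (0.03, -0.22, 0.28)},
}


def classify_published_example(drug_entry: dict,
                               disease: str) -> tuple[SignalClass,
                                                      SignalClass]:
    """SSA and DPA classes from literal interval inputs."""
    entry = drug_entry[disease]
    results = [ssa.SsaResult(drug="", disease=disease, window=w,
                             n_after=0, n_before=0, n_same_month=0,
                             crude_sr=est, null_sr=1.0, asr=est,
                             ci_low=lo, ci_high=hi)
               for (w, est, lo, hi) in entry["asr"]]
    ssa_class = ssa.classify_ssa(results)
    est, lo, hi = entry["ror"]
    ror_res = dpa.EstimateWithCI(est, lo, hi, scale="ratio", alpha=0.05)
    est, lo, hi = entry["ic"]
    ic_res = dpa.EstimateWithCI(est, lo, hi, scale="log2", alpha=0.05)
    return ssa_class, dpa.classify_dpa(ror_res, ic_res)


def published_classification_study() -> dict:
    """Classify the literal published-style inputs and count matches.

    The three signal drugs should classify inverse on SSA and DPA
    (hence repositioning) for both diseases; the synthetic null control
    should classify none on every index.
    """
    from .integrate import combine_classes
    from .types import CombinedClass

    n_expected = n_match = 0
    for drug, per_disease in PUBLISHED_EXAMPLES.items():
        for disease in per_disease:
            s, d = classify_published_example(per_disease, disease)
            combined, _ = combine_classes(s, d)
            n_expected += 1
            n_match += combined is CombinedClass.REPOSITIONING_SIGNAL
    for disease in SYNTHETIC_NULL_EXAMPLE:
        s, d = classify_published_example(SYNTHETIC_NULL_EXAMPLE, disease)
        combined, _ = combine_classes(s, d)
        n_expected += 1
        n_match += (s is SignalClass.NONE and d is SignalClass.NONE
                    and combined is CombinedClass.NONE)
    return {"n_rows": n_expected, "n_matching": n_match,
            "all_match": n_match == n_expected}


# ---------------------------------------------------------------------------
# Signature study


def connectivity_recovery_study(seed: int, n_seeds: int = 20,
                                config: simulate.SimExpressionConfig | None
                                = None) -> dict:
    """Rank of a planted signature reversal in the connectivity screen.

    Each replicate generates biosets and a 50-member reference panel
    containing one exact reversal of the drug signature, derives the
    query signature with the standard DEG thresholds, and screens the
    panel.  Reports how often the planted reference ranks first (and is
    shortlisted at permutation p <= 0.05).
    """
    n_top = n_shortlisted = 0
    for i in range(n_seeds):
        child = _child_seed(seed, i)
        cfg = config or simulate.SimExpressionConfig(seed=child)
        if config is not None:
            cfg = simulate.SimExpressionConfig(
                **{**vars(config), "seed": child})
        sim = simulate.gen_biosets_frames(cfg)
        query = signatures.filter_degs(sim.drug_bioset)
        results = signatures.connectivity_screen(
            query, sim.reference_panel, seed=child)
        top = results[0]
        n_top += top.reference_id == sim.manifest["planted_reference"]
        n_shortlisted += any(
            r.reference_id == sim.manifest["planted_reference"]
            and r.shortlisted for r in results)
    return {"n_seeds": n_seeds, "top1_rate": n_top / n_seeds,
            "shortlist_rate": n_shortlisted / n_seeds}
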