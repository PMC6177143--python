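"""Synthetic claims streams, report corpora, and expression biosets.

Every generator plants known effects and writes a ground-truth manifest
so downstream estimates can be checked for recovery:

* :func:`gen_claims` — monthly Bernoulli first-event hazards per
  patient (claims resolution is monthly, so no continuous-time model);
  the diagnosis hazard is multiplied by the planted rate ratio ``rho``
  from the drug-initiation month onward; a configurable fraction of
  drug users is made prevalent (first prescription inside the run-in)
  so the incident-user filter must remove them; enrollment may be
  staggered.
* :func:`gen_reports` — reports sample drugs independently from
  marginal probabilities and sample events with the reporting rate
  multiplied by the planted odds multiplier when a planted drug is
  present (at pair granularity that rate ratio is the per-pair
  reporting odds ratio); a duplicate fraction emits extra report
  versions sharing a case number.
* :func:`gen_biosets` — a disease bioset with a planted up-regulated
  gene set, a drug bioset reversing a stated fraction of it, a
  reference ranking panel containing one planted reversal of the drug
  signature, and a GMT collection with the planted set among decoys.

All draws go through one ``numpy`` generator per call; identical config
plus seed gives byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .faers import ContingencyTable, ReportSet
from .signatures import Bioset, write_bioset, write_gmt


def hazard_profile(shape: str, n_months: int, start: float,
                   end: float | None = None) -> np.ndarray:
    """Monthly hazard sequence: ``flat`` or ``linear`` from start to end."""
    if shape == "flat":
        return np.full(n_months, start, dtype=float)
    if shape == "linear":
        if end is None:
            raise ValueError("linear profile needs an end value")
        return np.linspace(start, end, n_months)
    raise ValueError(f"unknown hazard shape {shape!r}")


# ---------------------------------------------------------------------------
# Claims


@dataclass
class SimClaimsConfig:
    """Planted-truth configuration for a synthetic claims cohort.

    ``drug_hazards`` / ``dx_hazards`` map each code to its monthly
    first-event hazard sequence; ``effects`` maps (drug, disease) to
    the multiplicative diagnosis-hazard ratio ``rho`` applied from the
    initiation month onward.  ``prevalent_fraction`` is the fraction of
    each drug's users whose first observed prescription falls inside the
    run-in window (prevalent users the incident filter must drop);
    natural early initiators count toward it, the remainder is planted
    by relocating later initiations.
    """

    n_patients: int
    n_months: int
    drug_hazards: dict[str, np.ndarray]
    dx_hazards: dict[str, np.ndarray]
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    prevalent_fraction: float = 0.0
    stagger_fraction: float = 0.0
    max_enroll_month: int = 0
    run_in_months: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name, hazards in (("drug", self.drug_hazards),
                              ("dx", self.dx_hazards)):
            for code, h in hazards.items():
                h = np.asarray(h, dtype=float)
                if len(h) != self.n_months:
                    raise ValueError(f"{name} hazard for {code}: length "
                                     f"{len(h)} != n_months")
                if (h < 0).any() or (h > 1).any():
                    raise ValueError(f"{name} hazard for {code} outside [0,1]")
                hazards[code] = h
        for pair, rho in self.effects.items():
            if rho <= 0:
                raise ValueError(f"rho for {pair} must be > 0")
        if not 0 <= self.prevalent_fraction < 1:
            raise ValueError("prevalent_fraction in [0, 1)")

    @classmethod
    def single(cls, n_patients: int, n_months: int, drug_hazard: np.ndarray,
               dx_hazard: np.ndarray, rho: float = 1.0,
               **kwargs) -> "SimClaimsConfig":
        """One drug, one disease, one planted rate ratio."""
        return cls(n_patients=n_patients, n_months=n_months,
                   drug_hazards={"DRUG": np.asarray(drug_hazard, float)},
                   dx_hazards={"DX": np.asarray(dx_hazard, float)},
                   effects={("DRUG", "DX"): rho}, **kwargs)


@dataclass
class SimClaims:
    """In-memory result of one claims simulation."""

    events: pd.DataFrame       # patient_id, month, kind, code
    enrollment: pd.DataFrame   # patient_id, enroll_month, disenroll_month
    manifest: dict


def _first_months_from_calendar_hazard(hazard: np.ndarray,
                                       enroll: np.ndarray,
                                       rng: np.random.Generator) -> np.ndarray:
    """First-event month per patient under a shared calendar hazard.

    Exact inverse-CDF sampling of the discrete time-to-event
    distribution with per-patient left truncation at enrollment.
    Returns -1 where no event occurs inside the study period.
    """
    n_months = len(hazard)
    a = -np.cumsum(np.log1p(-hazard))          # a[m] = -log S(0..m)
    a_prev = np.concatenate([[0.0], a])[enroll]  # -log S up to enroll-1
    u = rng.random(len(enroll))
    target = a_prev - np.log(u)
    month = np.searchsorted(a, target, side="right")
    month[month >= n_months] = -1
    return month


def _first_months_from_hazard_matrix(hazard: np.ndarray,
                                     rng: np.random.Generator) -> np.ndarray:
    """First-event month per patient from an (n, M) hazard matrix."""
    log_surv = np.cumsum(np.log1p(-hazard), axis=1)
    u = rng.random(hazard.shape[0])
    hit = log_surv < np.log(u)[:, None]
    has = hit.any(axis=1)
    month = np.where(has, hit.argmax(axis=1), -1)
    return month


def gen_claims_frames(config: SimClaimsConfig) -> SimClaims:
    rng = np.random.default_rng(config.seed)
    n, n_months = config.n_patients, config.n_months

    enroll = np.zeros(n, dtype=int)
    if config.stagger_fraction > 0 and config.max_enroll_month > 0:
        n_late = round(config.stagger_fraction * n)
        late = rng.choice(n, size=n_late, replace=False)
        enroll[late] = rng.integers(1, config.max_enroll_month + 1,
                                    size=n_late)

    # Drug initiations.  prevalent_fraction is the fraction of each
    # drug's users whose FIRST OBSERVED prescription falls inside the
    # run-in (so the incident-user filter removes exactly that share):
    # early incident initiators already count toward it, and the
    # remainder is planted by relocating later initiations.
    init_month: dict[str, np.ndarray] = {}
    n_prevalent: dict[str, int] = {}
    for code, hazard in config.drug_hazards.items():
        month = _first_months_from_calendar_hazard(hazard, enroll, rng)
        users = np.flatnonzero(month >= 0)
        target = round(config.prevalent_fraction * len(users))
        if config.run_in_months > 0 and len(users):
            inside = month[users] < enroll[users] + config.run_in_months
            k = max(0, target - int(inside.sum()))
            eligible = users[~inside]
            if k and len(eligible):
                chosen = rng.choice(eligible, size=min(k, len(eligible)),
                                    replace=False)
                offset = rng.integers(0, config.run_in_months,
                                      size=len(chosen))
                month[chosen] = np.minimum(enroll[chosen] + offset,
                                           n_months - 1)
        n_prevalent[code] = target if config.run_in_months > 0 else 0
        init_month[code] = month

    # Diagnoses: hazard matrix with rho applied after planted initiations
    months_idx = np.arange(n_months)
    not_enrolled = months_idx[None, :] < enroll[:, None]
    dx_month: dict[str, np.ndarray] = {}
    for disease, base in config.dx_hazards.items():
        hazard = np.broadcast_to(base, (n, n_months)).copy()
        for (drug, dis), rho in config.effects.items():
            if dis != disease or rho == 1.0:
                continue
            init = init_month[drug]
            exposed = (init[:, None] >= 0) & (months_idx[None, :]
                                              >= init[:, None])
            hazard[exposed] *= rho
        np.clip(hazard, 0.0, 1.0, out=hazard)
        hazard[not_enrolled] = 0.0
        dx_month[disease] = _first_months_from_hazard_matrix(hazard, rng)

    pid = np.array([f"P{i:07d}" for i in range(n)])
    frames = []
    for code, month in init_month.items():
        has = month >= 0
        frames.append(pd.DataFrame({
            "patient_id": pid[has], "month": month[has],
            "kind": "prescription", "code": code}))
    for code, month in dx_month.items():
        has = month >= 0
        frames.append(pd.DataFrame({
            "patient_id": pid[has], "month": month[has],
            "kind": "diagnosis", "code": code}))
    events = (pd.concat(frames, ignore_index=True)
              .sort_values(["patient_id", "month", "kind", "code"],
                           kind="mergesort", ignore_index=True))
    enrollment = pd.DataFrame({"patient_id": pid, "enroll_month": enroll,
                               "disenroll_month": n_months})
    manifest = {
        "kind": "claims",
        "n_patients": n, "n_months": n_months,
        "run_in_months": config.run_in_months,
        "seed": config.seed,
        "drug_hazards": {k: list(v) for k, v in
                         config.drug_hazards.items()},
        "dx_hazards": {k: list(v) for k, v in config.dx_hazards.items()},
        "effects": {f"{d}|{s}": rho
                    for (d, s), rho in config.effects.items()},
        "prevalent_fraction": config.prevalent_fraction,
        "n_prevalent_relocated": n_prevalent,
        "n_drug_users": {k: int((v >= 0).sum())
                         for k, v in init_month.items()},
    }
    return SimClaims(events=events, enrollment=enrollment, manifest=manifest)


def gen_claims(config: SimClaimsConfig, out_dir: str | Path) -> SimClaims:
    """Simulate and write the claims-store input files plus manifest."""
    sim = gen_claims_frames(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rx = sim.events[sim.events["kind"] == "prescription"]
    dx = sim.events[sim.events["kind"] == "diagnosis"]
    rx.rename(columns={"code": "drug_code"})[
        ["patient_id", "month", "drug_code"]].to_csv(
        out / "prescriptions.tsv", sep="\t", index=False)
    dx.rename(columns={"code": "condition_code"})[
        ["patient_id", "month", "condition_code"]].to_csv(
        out / "diagnoses.tsv", sep="\t", index=False)
    sim.enrollment.to_csv(out / "enrollment.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(
        json.dumps(sim.manifest, indent=2, sort_keys=True) + "\n")
    return sim


# ---------------------------------------------------------------------------
# Reports


@dataclass
class SimReportsConfig:
    """Planted-truth configuration for a synthetic report corpus."""

    n_reports: int
    drugs: list[tuple[str, float]]             # (code, marginal prob)
    events: list[tuple[str, float]]            # (code, marginal prob)
    planted: list[tuple[str, str, float]] = field(default_factory=list)
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for code, p in [*self.drugs, *self.events]:
            if not 0 < p < 1:
                raise ValueError(f"marginal for {code} outside (0, 1)")
        for drug, event, mult in self.planted:
            if mult <= 0:
                raise ValueError(f"odds multiplier for ({drug}, {event}) "
                                 "must be > 0")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction in [0, 1)")


@dataclass
class SimReports:
    reports: ReportSet
    drug_dict: dict[str, str]
    event_dict: dict[str, str]
    manifest: dict


def _raw_drug(code: str) -> str:
    return f"{code} tablets"


def _raw_event(code: str) -> str:
    return f"{code} reaction"


def gen_reports_frames(config: SimReportsConfig) -> SimReports:
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drug_codes = [c for c, _ in config.drugs]
    event_codes = [c for c, _ in config.events]
    p_drug = np.array([p for _, p in config.drugs])
    p_event = np.array([p for _, p in config.events])

    x = rng.random((n, len(drug_codes))) < p_drug  # drug presence
    # The multiplier scales the event's reporting rate given the drug.
    # At pair granularity the ROR compares the target event against
    # other-reaction pairs on both sides of the table, so this rate
    # ratio is exactly the per-pair reporting odds ratio being planted.
    log_mult = np.zeros((len(drug_codes), len(event_codes)))
    for drug, event, mult in config.planted:
        log_mult[drug_codes.index(drug), event_codes.index(event)] \
            = np.log(mult)
    probs = np.minimum(p_event[None, :] * np.exp(x @ log_mult), 0.99)
    y = rng.random((n, len(event_codes))) < probs

    width = len(str(n * 2))
    report_id = np.array([f"R{i:0{width}d}" for i in range(1, n + 1)])
    case_id = np.array([f"C{i:0{width}d}" for i in range(1, n + 1)])

    rep_idx, drug_idx = np.nonzero(x)
    drugs = pd.DataFrame({
        "report_id": report_id[rep_idx],
        "drugname": [_raw_drug(drug_codes[j]) for j in drug_idx]})
    rep_idx, event_idx = np.nonzero(y)
    reactions = pd.DataFrame({
        "report_id": report_id[rep_idx],
        "pt": [_raw_event(event_codes[j]) for j in event_idx]})
    demo = pd.DataFrame({"report_id": report_id, "case_id": case_id})

    # Duplicate case versions: exact copies under a greater report_id
    k = round(config.duplicate_fraction * n)
    if k:
        dup = np.sort(rng.choice(n, size=k, replace=False))
        dup_report_id = np.array(
            [f"R{n + i:0{width}d}" for i in range(1, k + 1)])
        demo = pd.concat([demo, pd.DataFrame({
            "report_id": dup_report_id, "case_id": case_id[dup]})],
            ignore_index=True)
        remap = dict(zip(report_id[dup], dup_report_id))
        for df_name, df in (("drugs", drugs), ("reactions", reactions)):
            copies = df[df["report_id"].isin(remap)].copy()
            copies["report_id"] = copies["report_id"].map(remap)
            if df_name == "drugs":
                drugs = pd.concat([drugs, copies], ignore_index=True)
            else:
                reactions = pd.concat([reactions, copies], ignore_index=True)

    # True value of the pair-level ROR estimand for each planted pair.
    # Comparator (other-drug) pairs come from reports that co-mention
    # the planted drug with probability = its marginal, so their event
    # rate is partially shifted too ("masking"):
    #   implied OR = m / (1 - p_drug + p_drug * m).
    p_drug_by_code = dict(config.drugs)
    implied = {
        f"{drug}|{event}":
            mult / (1 - p_drug_by_code[drug] + p_drug_by_code[drug] * mult)
        for drug, event, mult in config.planted}
    manifest = {
        "kind": "reports",
        "n_reports": n,
        "seed": config.seed,
        "drugs": config.drugs,
        "events": config.events,
        "planted": [list(p) for p in config.planted],
        "implied_pair_or": implied,
        "duplicate_fraction": config.duplicate_fraction,
        "n_duplicates": k,
    }
    return SimReports(
        reports=ReportSet(demo=demo, drugs=drugs, reactions=reactions),
        drug_dict={_raw_drug(c).lower(): c for c in drug_codes},
        event_dict={_raw_event(c).lower(): c for c in event_codes},
        manifest=manifest)


def gen_reports(config: SimReportsConfig, out_dir: str | Path) -> SimReports:
    """Simulate and write DEMO/DRUG/REAC tables, dictionaries, manifest."""
    sim = gen_reports_frames(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim.reports.demo.to_csv(out / "demo.tsv", sep="\t", index=False)
    sim.reports.drugs.to_csv(out / "drug.tsv", sep="\t", index=False)
    sim.reports.reactions.to_csv(out / "reac.tsv", sep="\t", index=False)
    for name, mapping in (("drug_dict.tsv", sim.drug_dict),
                          ("event_dict.tsv", sim.event_dict)):
        pd.DataFrame({"raw_term": list(mapping),
                      "code": list(mapping.values())}).to_csv(
            out / name, sep="\t", index=False)
    (out / "manifest.json").write_text(
        json.dumps(sim.manifest, indent=2, sort_keys=True) + "\n")
    return sim


def gen_tables(n_tables: int, n_pairs: int, p_drug: float, p_event: float,
               odds_multiplier: float, seed: int = 0,
               ) -> list[ContingencyTable]:
    """Multinomial 2x2 pair tables with an exact planted reporting OR.

    The event probability given the drug is shifted on the log-odds
    scale, so the population odds ratio equals ``odds_multiplier``
    exactly; margins are approximately ``p_drug`` and ``p_event``.
    """
    rng = np.random.default_rng(seed)
    p_e_given_d = expit(logit(p_event) + np.log(odds_multiplier))
    probs = np.array([
        p_drug * p_e_given_d,
        p_drug * (1 - p_e_given_d),
        (1 - p_drug) * p_event,
        (1 - p_drug) * (1 - p_event),
    ])
    probs /= probs.sum()
    draws = rng.multinomial(n_pairs, probs, size=n_tables)
    return [ContingencyTable(*map(int, row)) for row in draws]


# ---------------------------------------------------------------------------
# Expression


@dataclass
class SimExpressionConfig:
    """Planted-truth configuration for synthetic expression evidence."""

    n_genes: int = 5000
    disease_up_size: int = 100
    drug_up_size: int = 80
    reversal_fraction: float = 0.8
    panel_size: int = 50
    n_gene_sets: int = 50
    gene_set_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.disease_up_size + self.drug_up_size > self.n_genes:
            raise ValueError("planted sets exceed gene universe")
        if not 0 <= self.reversal_fraction <= 1:
            raise ValueError("reversal_fraction in [0, 1]")
        if self.gene_set_size > self.n_genes:
            raise ValueError("gene_set_size exceeds gene universe")


@dataclass
class SimExpression:
    disease_bioset: Bioset
    drug_bioset: Bioset
    reference_panel: dict[str, list[str]]
    gene_sets: dict[str, frozenset]
    manifest: dict


def _noise_bioset(genes: np.ndarray, rng: np.random.Generator,
                  label: str) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": genes,
        "effect": rng.normal(0.0, 0.3, size=len(genes)),
        "p_value": rng.uniform(0.0, 1.0, size=len(genes)),
    })


def _plant(table: pd.DataFrame, genes: Sequence[str], sign: int,
           rng: np.random.Generator) -> None:
    idx = table["gene_id"].isin(genes)
    k = int(idx.sum())
    table.loc[idx, "effect"] = sign * rng.normal(1.5, 0.2, size=k)
    table.loc[idx, "p_value"] = 10.0 ** rng.uniform(-6, -2.5, size=k)


def gen_biosets_frames(config: SimExpressionConfig) -> SimExpression:
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"g{i:05d}" for i in range(config.n_genes)])

    special = rng.choice(config.n_genes,
                         size=config.disease_up_size + config.drug_up_size,
                         replace=False)
    disease_up = genes[special[:config.disease_up_size]]
    drug_up = genes[special[config.disease_up_size:]]
    n_rev = round(config.reversal_fraction * config.disease_up_size)
    reversed_genes = disease_up[
        rng.permutation(config.disease_up_size)[:n_rev]]

    disease_table = _noise_bioset(genes, rng, "disease")
    _plant(disease_table, disease_up, +1, rng)
    drug_table = _noise_bioset(genes, rng, "drug")
    _plant(drug_table, reversed_genes, -1, rng)
    _plant(drug_table, drug_up, +1, rng)

    disease_bioset = Bioset(disease_table, scale="log2", label="disease")
    drug_bioset = Bioset(drug_table, scale="log2", label="drug")

    # Reference panel: one exact reversal of the planted drug signature
    # (drug-down genes ranked top, drug-up genes bottom) among noise
    # permutations.
    query_down = set(reversed_genes)
    query_up = set(drug_up)
    middle = np.array([g for g in genes
                       if g not in query_down and g not in query_up])
    reversal = [*rng.permutation(sorted(query_down)),
                *rng.permutation(middle),
                *rng.permutation(sorted(query_up))]
    panel: dict[str, list[str]] = {}
    planted_idx = int(rng.integers(config.panel_size))
    for i in range(config.panel_size):
        ref_id = f"ref_{i:03d}"
        if i == planted_idx:
            panel[ref_id] = [str(g) for g in reversal]
        else:
            panel[ref_id] = [str(g) for g in rng.permutation(genes)]

    gene_sets: dict[str, frozenset] = {}
    planted_set_idx = int(rng.integers(config.n_gene_sets))
    for i in range(config.n_gene_sets):
        name = f"GS_{i:03d}"
        if i == planted_set_idx:
            gene_sets[name] = frozenset(str(g) for g in disease_up)
        else:
            gene_sets[name] = frozenset(
                str(g) for g in genes[rng.choice(
                    config.n_genes, size=config.gene_set_size,
                    replace=False)])

    manifest = {
        "kind": "expression",
        "seed": config.seed,
        "n_genes": config.n_genes,
        "disease_up": sorted(str(g) for g in disease_up),
        "drug_up": sorted(str(g) for g in drug_up),
        "drug_reversed": sorted(str(g) for g in reversed_genes),
        "reversal_fraction": config.reversal_fraction,
        "planted_reference": f"ref_{planted_idx:03d}",
        "planted_gene_set": f"GS_{planted_set_idx:03d}",
    }
    return SimExpression(disease_bioset=disease_bioset,
                         drug_bioset=drug_bioset,
                         reference_panel=panel, gene_sets=gene_sets,
                         manifest=manifest)


def gen_biosets(config: SimExpressionConfig,
                out_dir: str | Path) -> SimExpression:
    """Simulate and write biosets, panel rankings, GMT, and manifest."""
    sim = gen_biosets_frames(config)
    out = Path(out_dir)
    (out / "panel").mkdir(parents=True, exist_ok=True)
    write_bioset(sim.disease_bioset, out / "disease.bioset.tsv")
    write_bioset(sim.drug_bioset, out / "drug.bioset.tsv")
    for ref_id, ranking in sim.reference_panel.items():
        (out / "panel" / f"{ref_id}.txt").write_text(
            "\n".join(ranking) + "\n")
    write_gmt(sim.gene_sets, out / "genesets.gmt")
    (out / "manifest.json").write_text(
        json.dumps(sim.manifest, indent=2, sort_keys=True) + "\n")
    return sim
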