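"""Transcriptome cross-validation of repositioning signals.

A *bioset* is a per-gene differential-expression table (signed effect
plus p-value) for one comparison.  The stage derives signed up/down
gene signatures at the usual thresholds (p <= 0.05, |fold change| >=
1.5, with a p-only mode for sparse signatures), scores opposing
disease/drug overlap (genes up in disease and down after drug) with
one-sided hypergeometric enrichment, ranks gene-set (pathway)
enrichment with a documented surrogate overall score — the sum of
-log10 hypergeometric p across signatures, standing in for proprietary
meta-analysis scores that are not published — and screens a query
signature against a reference panel of ranked expression profiles with
the classic two-tag KS connectivity score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EFFECT_SCALES = ("linear", "log2")


@dataclass
class Bioset:
    """One differential-expression comparison.

    ``effect`` is a signed fold change on the declared scale:
    ``linear`` (e.g. +2.0 = doubled, -2.0 = halved) or ``log2``.
    """

    table: pd.DataFrame  # gene_id, effect, p_value
    scale: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.scale not in EFFECT_SCALES:
            raise ValueError(f"undeclared or unknown effect scale "
                             f"{self.scale!r}; use one of {EFFECT_SCALES}")
        t = self.table
        if t["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id within bioset")
        p = t["p_value"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p_value outside [0, 1]")


@dataclass(frozen=True)
class SignedGeneSignature:
    """Disjoint up/down gene sets with the thresholds that produced them."""

    up: frozenset
    down: frozenset
    p_max: float = 0.05
    fc_min: float | None = 1.5

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")


@dataclass
class ConnectivityResult:
    """One reference profile's match to the query signature."""

    reference_id: str
    raw_score: float
    normalized_score: float
    permutation_p: float
    shortlisted: bool = False


def read_bioset(path: str | Path) -> Bioset:
    """Read a bioset TSV whose first line is a ``# scale=... label=...``
    sidecar header, followed by gene_id/effect/p_value columns."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#"):
        raise ValueError(f"{path}: missing sidecar header line "
                         "('# scale=linear|log2 ...')")
    meta = dict(item.split("=", 1) for item in first.lstrip("# ").split()
                if "=" in item)
    if "scale" not in meta:
        raise ValueError(f"{path}: sidecar header lacks scale=")
    table = pd.read_csv(path, sep="\t", skiprows=1,
                        dtype={"gene_id": str})
    return Bioset(table=table, scale=meta["scale"],
                  label=meta.get("label", path.stem))


def write_bioset(bioset: Bioset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scale={bioset.scale} label={bioset.label}\n")
        bioset.table.to_csv(fh, sep="\t", index=False)


def filter_degs(bioset: Bioset, p_max: float = 0.05,
                fc_min: float | None = 1.5) -> SignedGeneSignature:
    """Signed DEG signature at p and fold-change thresholds.

    ``fc_min`` is on the linear scale regardless of the bioset's
    declared effect scale; ``fc_min=None`` disables the fold-change
    cutoff (p-only mode, useful when a signature would otherwise be too
    sparse to use).  Relaxing either threshold never shrinks the sets.
    """
    t = bioset.table
    passing = t["p_value"] <= p_max
    if fc_min is not None:
        if fc_min <= 0:
            raise ValueError("fc_min must be positive")
        if bioset.scale == "log2":
            passing &= t["effect"].abs() >= math.log2(fc_min)
        else:
            passing &= t["effect"].abs() >= fc_min
    sub = t[passing]
    return SignedGeneSignature(
        up=frozenset(sub.loc[sub["effect"] > 0, "gene_id"]),
        down=frozenset(sub.loc[sub["effect"] < 0, "gene_id"]),
        p_max=p_max, fc_min=fc_min)


def hypergeom_enrichment_p(k: int, universe: int, set1: int,
                           set2: int) -> float:
    """One-sided P(overlap >= k) for two sets drawn from ``universe``."""
    if min(set1, set2) == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe, set1, set2))


@dataclass
class OpposingOverlap:
    """Counts and enrichment of the two opposing-direction overlaps."""

    n_up_down: int       # disease-up ∩ drug-down
    n_down_up: int       # disease-down ∩ drug-up
    p_up_down: float
    p_down_up: float
    combined_score: float


def opposing_overlap(disease_sig: SignedGeneSignature,
                     drug_sig: SignedGeneSignature,
                     universe_size: int) -> OpposingOverlap:
    """Score signature opposition: disease-up genes reversed by the drug.

    Each direction gets a one-sided hypergeometric enrichment p; the
    combined score is ``-log10(p_ud) - log10(p_du)`` (larger = stronger
    reversal).
    """
    sets = [disease_sig.up, disease_sig.down, drug_sig.up, drug_sig.down]
    if universe_size < max((len(s) for s in sets), default=0):
        raise ValueError("universe smaller than a gene set")
    n_ud = len(disease_sig.up & drug_sig.down)
    n_du = len(disease_sig.down & drug_sig.up)
    p_ud = hypergeom_enrichment_p(n_ud, universe_size,
                                  len(disease_sig.up), len(drug_sig.down))
    p_du = hypergeom_enrichment_p(n_du, universe_size,
                                  len(disease_sig.down), len(drug_sig.up))
    return OpposingOverlap(
        n_up_down=n_ud, n_down_up=n_du, p_up_down=p_ud, p_down_up=p_du,
        combined_score=-math.log10(p_ud) - math.log10(p_du))


def read_gmt(path: str | Path) -> dict[str, frozenset]:
    """GMT gene sets: name <tab> description <tab> members..."""
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT row needs >= 3 fields")
            members = frozenset(g for g in parts[2:] if g)
            if not members:
                raise ValueError(f"{path}:{line_no}: empty gene set")
            sets[parts[0]] = members
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def geneset_score(signature: SignedGeneSignature,
                  gene_sets: Mapping[str, frozenset],
                  universe_size: int) -> pd.DataFrame:
    """Hypergeometric enrichment of the signature in each gene set.

    The signature's up and down genes are pooled for the per-set test.
    Rows are ranked by descending ``-log10 p`` (most enriched first).
    """
    genes = signature.up | signature.down
    rows = []
    for name, members in gene_sets.items():
        k = len(genes & members)
        p = hypergeom_enrichment_p(k, universe_size, len(genes), len(members))
        rows.append({"gene_set": name, "set_size": len(members),
                     "overlap": k, "p_value": p,
                     "neg_log10_p": -math.log10(p) if p > 0 else math.inf})
    out = pd.DataFrame(rows).sort_values(
        ["neg_log10_p", "gene_set"], ascending=[False, True],
        ignore_index=True)
    return out


def surrogate_overall_score(enrichment_tables: Sequence[pd.DataFrame],
                            ) -> pd.DataFrame:
    """Per-set score summed across signatures: sum of -log10 p.

    This is a documented surrogate for proprietary meta-analysis
    "overall" scores, NOT a reimplementation of any such algorithm; it
    rewards gene sets enriched consistently across all the supplied
    signatures (e.g. up in disease and reversed by every candidate
    drug).
    """
    merged = None
    for i, table in enumerate(enrichment_tables):
        part = table[["gene_set", "neg_log10_p"]].rename(
            columns={"neg_log10_p": f"score_{i}"})
        merged = part if merged is None else merged.merge(part, on="gene_set")
    score_cols = [c for c in merged.columns if c.startswith("score_")]
    merged["surrogate_overall_score"] = merged[score_cols].sum(axis=1)
    return merged.sort_values(
        ["surrogate_overall_score", "gene_set"], ascending=[False, True],
        ignore_index=True)


def _ks_tag_statistic(tag_ranks: np.ndarray, n: int) -> float:
    """Two-sided KS statistic of one tag set against a ranking of n genes.

    ``tag_ranks`` are 1-based positions (1 = most up-regulated) of the
    ``t`` tags.  With V(1) <= ... <= V(t) the up-running and
    down-running deviations are
    ``a = max_j (j/t - V(j)/n)`` and ``b = max_j (V(j)/n - (j-1)/t)``;
    the statistic is ``a`` if ``a > b`` else ``-b``.
    """
    v = np.sort(np.asarray(tag_ranks, dtype=np.float64))
    t = len(v)
    j = np.arange(1, t + 1, dtype=np.float64)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1) / t)
    return float(a) if a > b else float(-b)


def connectivity_score(query_up: Sequence[str], query_down: Sequence[str],
                       reference_ranked_list: Sequence[str]) -> float:
    """Raw CMAP-style connectivity of an up/down query to one reference.

    The reference is a total ranking of the gene universe (first = most
    up-regulated under the reference perturbation).  The raw score is
    ``ks_up - ks_down``; when both tag statistics share a sign the
    signature straddles the profile inconsistently and the score is 0.
    Positive = reference mimics the query, negative = reverses it.
    """
    if not query_up or not query_down:
        raise ValueError("query tag sets must be non-empty")
    rank_of = {g: i + 1 for i, g in enumerate(reference_ranked_list)}
    missing = [g for g in [*query_up, *query_down] if g not in rank_of]
    if missing:
        raise ValueError(f"tags absent from reference universe: "
                         f"{sorted(missing)[:10]}")
    n = len(reference_ranked_list)
    ks_up = _ks_tag_statistic(
        np.array([rank_of[g] for g in query_up]), n)
    ks_down = _ks_tag_statistic(
        np.array([rank_of[g] for g in query_down]), n)
    if ks_up * ks_down > 0:
        return 0.0
    return ks_up - ks_down


def _permutation_null(n: int, t_up: int, t_down: int, n_permutations: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Null |raw score| distribution for random tag sets of matched sizes.

    Under the null the tag positions are uniform random ranks, so the
    distribution depends only on (n, t_up, t_down) and is shared across
    every reference in a panel.
    """
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        ranks = rng.choice(n, size=t_up + t_down, replace=False) + 1
        ks_u = _ks_tag_statistic(ranks[:t_up], n)
        ks_d = _ks_tag_statistic(ranks[t_up:], n)
        out[i] = 0.0 if ks_u * ks_d > 0 else ks_u - ks_d
    return np.abs(out)


def connectivity_screen(query_sig: SignedGeneSignature,
                        reference_panel: Mapping[str, Sequence[str]],
                        n_permutations: int = 1000,
                        shortlist_p: float = 0.05,
                        seed: int | np.random.Generator = 0,
                        ) -> list[ConnectivityResult]:
    """Score a query signature against every reference profile.

    ``normalized_score`` is raw / max |raw| over the panel (sign
    preserved, in [-1, 1]); ``permutation_p`` comes from >= 1000
    size-matched random tag-set draws (two-sided on |raw|, one shared
    null per panel since all references have the same universe).
    Results are ranked by descending |normalized| and shortlisted at
    ``permutation_p <= shortlist_p``.
    """
    if len(reference_panel) < 2:
        raise ValueError("panel needs at least 2 reference rankings")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    up = sorted(query_sig.up)
    down = sorted(query_sig.down)
    raw = {ref_id: connectivity_score(up, down, ranking)
           for ref_id, ranking in reference_panel.items()}
    max_abs = max(abs(v) for v in raw.values())
    degenerate = max_abs == 0

    sizes = {len(ranking) for ranking in reference_panel.values()}
    nulls = {n: _permutation_null(n, len(up), len(down), n_permutations, rng)
             for n in sizes}
    results = []
    for ref_id, ranking in reference_panel.items():
        null = nulls[len(ranking)]
        p = float((1 + np.sum(null >= abs(raw[ref_id])))
                  / (n_permutations + 1))
        results.append(ConnectivityResult(
            reference_id=ref_id,
            raw_score=raw[ref_id],
            normalized_score=0.0 if degenerate else raw[ref_id] / max_abs,
            permutation_p=p,
            shortlisted=(not degenerate) and p <= shortlist_p))
    results.sort(key=lambda r: (-abs(r.normalized_score), r.reference_id))
    return results


def read_ranked_list(path: str | Path) -> list[str]:
    """One gene_id per line, rank order (1 = most up-regulated)."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if len(genes) != len(set(genes)):
        raise ValueError(f"{path}: duplicate genes in ranking")
    return genes
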