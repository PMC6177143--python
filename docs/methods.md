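# Methods

`reposignals` mines *inverse* drug–outcome associations — a drug after
whose initiation a diagnosis is recorded less often than expected — as
candidate drug-repositioning signals, and cross-validates them with
transcriptome evidence. This note documents the statistical model of
each stage, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the known limitations.

## Sequence symmetry analysis (SSA)

**Model.** Time is discrete at monthly resolution over a half-open
study period `[0, M)`; calendar dates are mapped to month indices at
ingest, because claims are collected monthly and finer order within a
month is unobservable. For one drug and one diagnosis, the analysis
set is the patients with an incident occurrence of both, with the gap
`0 < |m_dx − m_drug| ≤ w` for a window `w ∈ {6, 12, 24, 36}` months.
The crude sequence ratio is

    SR(w) = n_after / n_before,

the ratio of patients diagnosed after versus before initiation.
Orientation: values below 1 mean fewer diagnoses after initiation,
so "ASR < 1 = inverse association" holds literally. Same-month pairs
are excluded from `n = n_after + n_before` (their order is
unobservable) but counted and reported.

**Incident-user restriction.** A first event is incident only if it
falls at or after `enroll_month + run_in` (default run-in 6 months,
applied identically to late enrollees). A first event inside the
run-in marks a prevalent user, who is excluded for that code — not
shifted to a later event. Patients without an enrollment record are
treated as enrolled at study start (counted and logged; an error
policy is available). The waiting-time histogram of first events is
emitted as a diagnostic: a flat curve (head/tail ratio ≈ 1) is
consistent with incident capture; an early spike flags prevalent
contamination. Disenrollment after the incident event does not
truncate ascertainment windows; the generator does not simulate
informative dropout, so nothing would be gained by modeling it here.

**Trend correction.** The crude SR is biased by secular trends in
either event stream. The null-effect SR is the SR expected under
independence given the observed monthly incident counts `d_m`
(initiations) and `o_m` (diagnoses):

    A = Σ_m d_m · Σ_{k=m+1..min(m+w, M−1)} o_k      (diagnosis after)
    B = Σ_m d_m · Σ_{k=max(0,m−w)..m−1} o_k          (diagnosis before)
    NSR(w) = A / B,

i.e. the probability ratio of the two orderings over independent
event-month pairs, truncated to the same window and study period as
the observed pairs (no partial-month weighting). `A` and `B` are
exact integer sums. The adjusted sequence ratio is `ASR = SR / NSR`,
so `ASR × NSR = SR` holds exactly whenever all three are defined.
The marginal counts entering the NSR are all incident events after
run-in filtering, not only paired patients.

**Exact confidence interval.** Conditional on `n`, `n_after` is
treated as Binomial(n, p) with `p/(1−p) = SR`. The Clopper–Pearson
bounds `(p_L, p_U)` at level `1−α` (beta-quantile form, via
`scipy.stats.beta`) map to

    CI(ASR) = ( p_L/(1−p_L)/NSR ,  p_U/(1−p_U)/NSR ).

`n_after = 0` gives a lower bound of 0; `n_after = n` gives an
infinite upper bound, flagged. `n_before = 0` flags the point
estimate as undefined without raising.

**Classification.** A drug–disease pair is an SSA *inverse signal*
when the interval lies entirely below 1 in at least 3 of the 4
windows; a *risk signal* mirrors that above 1; undefined windows count
as not significant. "Significant" means the CI excludes 1 — the
interval criterion, stated as an assumption since window-level
significance admits other readings. No multiple-testing adjustment is
applied across drugs or windows; the output records how many tests
were run.

## Disproportionality analysis (DPA)

**Counting.** Reports are deduplicated by case number, keeping the
numerically/lexicographically greatest report identifier (the latest
version; the retention rule is a documented choice — keeping the first
version would be equally defensible). Each report is expanded into
the cross-product of its mapped drugs and mapped reactions,
deduplicated within report, and the 2×2 table for a (drug, condition)
query counts *pairs*: `a` (drug & condition), `b` (drug, other
condition), `c` (other drug, condition), `d` (neither), with
`a+b+c+d = N` the corpus pair total. A report-based table is
available behind a separate function for sensitivity analysis.
Dictionary matching is case-insensitive and whitespace-normalized,
never fuzzy; unmapped terms pass through in an `unmapped:` namespace
so they stay visible.

**ROR.** `ROR = ad/bc` with the Woolf log-scale interval
`exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))`. Any zero cell triggers
Haldane's +0.5 on all four cells (flagged); a zero margin leaves the
estimate undefined. No exact small-sample interval is offered — the
Wald-type bound is the standard for this statistic.

**Information component.** Default method `bcpnn-1998`: the
closed-form posterior moments of `IC = log2 p_xy/(p_x p_y)` with
Beta(1,1) margins, Beta(2,·) totals, joint prior mass `γ11 = 1` and
`γ` tuned so the prior IC is centred at zero:

    E(IC) = log2 [ (a+1)(N+2)² / ((N+γ)(a+b+1)(a+c+1)) ],
    γ     = (N+2)² / ((a+b+1)(a+c+1)),

with the three-term posterior variance and a normal-quantile interval
`E ± z√V`. The alternative `gamma-smoothed` method is
`IC = log2((a+0.5)/(E+0.5))` with `E = (a+b)(a+c)/N` and a
gamma-posterior credible interval. Both are exposed because the
interval construction for the IC is not uniquely standardized; the
method name is stamped on every output row. Under independence
tables at `a ≈ 125`, measured coverage of 0 is ≈ 0.97 (bcpnn-1998)
and ≈ 0.96 (gamma-smoothed) — both near-nominal, the closed form
slightly conservative. Neither method needs a zero-cell correction
(shrinkage is built in).

**Classification.** DPA *inverse signal*: ROR 95% upper bound < 1
AND IC 95% upper bound < 0. Risk mirrors both above the null.
Undefined inputs propagate to an undefined class.

## Signal integration

`repositioning_signal` requires inverse classification from both SSA
and DPA. Inverse on exactly one method (other none/undefined) is
`inverse_one_method`; risk on either method (without inverse on the
other) is `risk`; inverse on one and risk on the other is
contradictory evidence, classified `none` with a conflict flag. The
matrix is a pure function of its inputs (deterministically sorted,
row-order invariant) and renders to a ▼/△/− symbol table plus the
full numeric tables, byte-identical across runs.

## Transcriptome cross-validation

**Signatures.** A bioset is a per-gene table (signed effect on a
declared linear or log2 scale, p-value). DEG signatures use
`p ≤ 0.05` and `|linear fold change| ≥ 1.5`; a p-only mode drops the
fold-change cutoff for comparisons that would otherwise yield too few
genes to analyze.

**Opposing overlap.** The repositioning hypothesis predicts genes up
in disease and down after drug. Both opposing intersections get a
one-sided hypergeometric enrichment p against the declared universe;
the combined score is `−log10 p_ud − log10 p_du`.

**Gene-set scores.** Per-set enrichment is the same hypergeometric
tail on the pooled (up ∪ down) signature. Across a list of
signatures, sets are ranked by the *surrogate overall score*
`Σ −log10 p`. This is an explicitly labelled surrogate: commercial
meta-analysis platforms compute proprietary correlation scores whose
algorithms are not published, so no reimplementation is possible or
attempted; the surrogate preserves the use made of such scores
(ranking sets consistently dysregulated across disease and drug
signatures).

**Connectivity.** A reference profile is a total ranking of the gene
universe (rank 1 = most up-regulated; ties broken by stable gene
order upstream). For a tag set of size `t` with sorted reference
ranks `V(j)`,

    a = max_j ( j/t − V(j)/n ),   b = max_j ( V(j)/n − (j−1)/t ),
    ks = a  if a > b  else −b,

and the raw connectivity score is `ks_up − ks_down`, set to 0 when
both tag statistics share a sign. Scores are normalized by the
panel's maximum |raw| (sign preserved, in [−1, 1]). The permutation
p-value draws ≥ 1000 random tag sets of matched sizes; because the
null depends only on `(n, t_up, t_down)`, one null sample is shared
across all references of a panel — statistically identical to
per-reference permutation and ~50× cheaper. References with
permutation p ≤ 0.05 are shortlisted.

## Synthetic data generator

The generator plants known effects and writes them to a ground-truth
manifest that tests and studies read back.

* **Claims** (`gen_claims`): per patient, first drug initiation and
  first diagnosis are drawn from monthly Bernoulli hazards (exact
  inverse-CDF sampling; discrete time matches the engine's monthly
  resolution). The diagnosis hazard is multiplied by the planted rate
  ratio `rho` from the initiation month onward (same-month
  coincidence allowed, exercising the tie-exclusion path).
  `prevalent_fraction` fixes the share of users whose first observed
  prescription falls inside the run-in; enrollment can be staggered.
* **Reports** (`gen_reports`): drugs are independent Bernoulli draws
  from marginal probabilities; a planted (drug, event, multiplier)
  triple multiplies the event's reporting rate when the drug is
  present. At pair granularity the noncase pairs are other-reaction
  pairs, so this rate ratio *is* the per-pair reporting OR being
  planted. Because background drugs co-occur independently,
  comparator pairs come from reports co-mentioning the planted drug
  at its marginal rate `p_d`, so the exact estimand is
  `m / (1 − p_d + p_d·m)` ("masking"); the manifest records this
  implied pair OR and recovery assertions target it. Duplicate case
  versions are exact copies under a greater report id (exercising the
  dedup retention rule).
* **Expression** (`gen_biosets`): a disease bioset with a planted
  up-set (log2 effects ≈ 1.5 ± 0.2, p ∈ 10^[−6,−2.5]), a drug bioset
  reversing a stated fraction of it plus its own up-set, noise genes
  with null effects and uniform p, a reference panel containing one
  exact reversal of the drug signature among random permutations, and
  a GMT collection with the planted set among size-matched decoys.

Identical config + seed yields byte-identical files.

**What the generator does not emulate:** confounding by indication,
protopathic bias, reporting-rate heterogeneity over time, stimulated
reporting, drug–drug co-prescription correlation in claims,
gene–gene correlation, and probe-level microarray structure. Passing
recovery studies therefore demonstrate correctness of the estimators
under their own assumptions, not robustness to these real-data
biases.

## Study conditions and default parameters

| Parameter | Default | Rationale |
|---|---|---|
| Study length `M` | 120 months | a decade-scale claims window |
| Run-in | 6 months | standard incident-user washout at monthly resolution |
| Windows | 6/12/24/36 months | the standard SSA interval ladder |
| α | 0.05 | conventional two-sided level |
| Initiation hazard | 0.002/month | ~20% of the cohort ever exposed; one drug reaching much more would be unrealistic, and heavy exposure feeds a true effect back into the outcome trend the NSR is estimated from (see limitations) |
| Diagnosis hazard | 0.003/month | high for a single condition (~30% lifetime) — the cohort emulates a comorbidity-enriched subpopulation so 50k patients yield ~10³ analyzable pairs per window |
| Cohort size | 50,000 patients (recovery studies), 40,000 (end-to-end) | keeps each study under a couple of minutes on one core while the window counts stay informative |
| Report corpus | 350,000 reports → ~2×10⁵ pairs (recovery), 50,000 (end-to-end) | FAERS-like sparsity: one drug in ~3% of reports, the target condition at a 2% marginal |
| Planted effects | rho 0.3–0.5; pair OR 0.25; reversal fraction 0.8 | strong but realistic signal sizes for a screen designed around high specificity |
| Connectivity panel | 5,000 genes, 50 references, 1000 permutations | keeps the screen ~0.1 s/reference at stable permutation p resolution |

The trend-correction study uses a 5-fold linearly rising initiation
hazard with flat outcome hazard and `rho = 1`, and reads the 36-month
window: with a flat outcome stream, an initiation trend biases the
crude SR only through study-boundary truncation, which grows with the
window (analytically ≈ −18% at w=36 versus ≈ −7% at w=12 for this
design). The rate-ratio recovery study reads the 24-month window,
where pair yield makes the exact interval informative.

## Numerical and degenerate-input choices

* Undefined ratios (zero denominators, zero margins) are flagged
  results, never exceptions; classification treats them as not
  significant.
* `n_after = n` maps to a +∞ upper ASR bound rather than a clipped
  value.
* NSR numerator/denominator are exact `int64` sums; equality with the
  brute-force enumeration is asserted exactly, not within tolerance.
* Haldane's correction applies to the ROR only, to all four cells at
  once, and is flagged on the output row.
* Permutation p-values use the add-one estimator `(1+k)/(1+n)` so
  they are never zero.
* Deduplication sorts with a stable mergesort on (case, version) so
  the retained report is deterministic under input permutation.
* Connectivity reference rankings must be total; missing query tags
  raise with the offending gene ids listed.

## Known limitations

* **Exposure feedback.** The NSR estimates the counterfactual trend
  from *observed* incident counts. When a drug truly changes the
  outcome rate and a large fraction of the cohort is exposed, the
  observed outcome trend itself absorbs part of the effect and the
  ASR is pulled toward the null (measured: ≈ +3% bias on rho = 0.5 at
  45% lifetime exposure, ≈ +1% at 20%). This is inherent to the
  marginal-trend formulation, not to this implementation.
* **Masking in pair-based DPA.** See the implied-pair-OR derivation
  above; at FAERS-like sparsity the distortion is ~1–2%.
* **Monthly ties.** Same-month pairs are discarded; a drug whose
  effect manifests within the initiation month is invisible to SSA
  at this resolution.
* **Conservative exact intervals.** Clopper–Pearson over-covers at
  small `n`; inverse-signal detection is correspondingly conservative
  in the smallest windows.
* The IC interval construction is not uniquely standardized; two
  documented variants are provided and stamped on outputs, and
  neither is asserted to be canonical.
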