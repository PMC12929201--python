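# Methods

This note documents the models, conventions and design choices behind
`gapvigil`, in the order of the analysis chain. Everything stated here is
computed by the package's tests or by `scripts/acceptance.py`; nothing is
quoted from external results.

## Label model and lexicon scanning

Study types form a constrained label set: PE (pharmaco-epidemiology) and CT
(clinical trial) are mutually exclusive — a paper analyzed as a randomized
trial is not simultaneously counted as an observational study — while PK
(pharmacokinetics) may accompany either, because trials and observational
studies often report drug exposure. `validate_study_labels` enforces this
everywhere labels enter.

Drug scanning uses a cleaned synonym vocabulary. Cleaning rules, in order:
case-fold and whitespace-normalize (NFKC); drop synonyms shorter than five
characters (short strings such as "ASA" match too promiscuously inside
unrelated words and abbreviations); drop dosage-like tokens (a number glued
to mg/ml/%/IU units); drop any synonym that survives in two or more entries
— ambiguity is resolved by exclusion, not priority, because a wrong
assignment is worse than a missed one. Matching is word-boundary,
case-insensitive and longest-synonym-first, so "supraspinatus" never
matches "aspirin". Drugs are scanned over title, abstract, keywords and
MeSH terms; populations over title, abstract and MeSH only (keywords are
author-supplied and dominated by methodological terms for populations);
diseases are taken directly from MeSH terms restricted to the C and F
branches of the MeSH tree.

Publication frequency is the number of **distinct records** mentioning a
drug, per (population tag, study type) cell. A record with d drugs, p
population tags and s study types contributes to d·p·s cells, once each.

Claims drug names are normalized by splitting multi-ingredient names on
"-", "/", ";", " with ", " and "; removing allergen/extract/vaccine/
prenatal-vitamin/lotion/kit categories outright; and stripping source
(human, bovine, ...), process (micronized, injection, ...) and
salt/formulation (hydrochloride, calcium, ...) tokens. Unmatched names pass
through lowercased rather than erroring, since claims vocabularies are
open-ended.

## Triage evaluation

Classifier input is the concatenation title ⊕ abstract ⊕ MeSH ⊕ keywords,
whitespace-tokenized and split into non-overlapping chunks of at most 512
tokens (the fixed input width of transformer-style encoders). The
classifier interface is `fit(chunks, labels)` / `predict_record(chunks)`;
the bundled reference implementation is a token-count logistic regression
whose chunk scores are **max-pooled** per record — pooling is a genuine
design choice, and max was chosen so that any positive chunk flags the
record, which favours recall, the quantity that matters when missed papers
mean missed evidence.

Each study type is evaluated as its own binary task — type-positive records
versus non-relevant records — under stratified k-fold cross-validation
(default k = 3) with a fixed seed, so every sample is predicted exactly
once as a held-out item. Metrics (accuracy, precision, recall, F1) are
reported both pooled over the union of test folds and per fold, since
either aggregation is defensible and they differ slightly on small folds.

**Calibration** is the re-review step: records whose cross-validated
prediction disagrees with their label are handed to a review function (a
human in practice, a truthful oracle in tests) that may correct exactly
those labels and no others; metrics are recomputed against the corrected
labels. With a truthful reviewer and a better-than-chance classifier this
cannot decrease pooled F1, and the test suite asserts the improvement on a
5 %-noise corpus for all three study types.

Inter-annotator agreement is **exact-tuple** agreement on (relevance,
full study-type set) — the strictest definition, chosen because a published
aggregate agreement rate does not decompose per label; disagreements are
resolved by a third annotator who must cover every disagreement id.

## Claims windowing and the knowledge gap

All dates are integer days from an arbitrary epoch; windows in this domain
are day counts, so no calendar arithmetic is used. The pregnancy **index
date** is the day of a person's first delivery code. Eligibility requires
enrollment spans covering [index−270, index+180] without a gap (adjacent
spans merge). The pregnancy prescription window is [index−270, index−1]
and postpartum is [index, index+180]: the index day itself is assigned to
postpartum, so the two windows partition the whole interval and every
in-range prescription is counted exactly once. Prescription counting is
event-level (each fill counts) by default, with person-level distinct
counting behind a flag; rates are n_prescriptions / sample size, also
reported per 1000 persons.

Pediatric age groups are [0, 1), [1, 12), [12, 18] years (half-open at the
shared boundaries, with 18 included in the oldest group); age is day
difference divided by 365. A person is assigned per year — sample sizes
accumulate across years using the mid-year age, and each prescription is
grouped by the age on its own day — so a child crossing a boundary
contributes to both groups in the appropriate years. Only drugs with
**strictly more than 10** prescriptions across the study years enter the
landscape.

Evidence classes per (drug, subpopulation, study type): **no evidence** =
0 papers, **weak** = 1–4, **adequate** ≥ 5. The knowledge gap of a cell is
(no + weak) / number of prescribed drugs in that subpopulation, with drugs
absent from the publication table counting as 0 papers. Claims
subpopulations map to literature population tags as pregnancy→pregnancy,
postpartum→postpartum, ped_0_1→infant, ped_1_12→children,
ped_12_18→adolescent. No-evidence drugs (0 papers in **all three** study
types) are ranked by prescription count, ties broken alphabetically.

The **miss probability** quantifies how likely a weak-evidence drug is to
be overlooked entirely by an imperfect per-paper classifier: with
per-paper recall r and n papers, P(miss all) = (1−r)ⁿ, reported as a
percentage. At r = 0.93 and n = 4 this is 0.0024 %, which is why a recall-
oriented classifier suffices for gap detection even without perfect
per-paper accuracy.

## Disproportionality statistics

All four statistics operate on report-level 2×2 tables (n₁₁ drug∧event,
n₁₀, n₀₁, n₀₀; N their sum; E = (n₁₁+n₁₀)(n₁₁+n₀₁)/N the expected
co-report count under independence).

- **PRR** = [n₁₁/(n₁₁+n₁₀)] / [n₀₁/(n₀₁+n₀₀)], interval on the log scale
  with SE = √(1/n₁₁ − 1/(n₁₁+n₁₀) + 1/n₀₁ − 1/(n₀₁+n₀₀)).
- **ROR** = n₁₁n₀₀/(n₁₀n₀₁), SE = √(1/n₁₁ + 1/n₁₀ + 1/n₀₁ + 1/n₀₀).
  Both lower bounds are the 2.5th percentile (95 % interval lower limit).
  Zero cells leave the bound undefined unless the continuity-correction
  flag (add 0.5 to every cell) is set; the flag is **off by default**.
- **IC** uses the gamma-Poisson shrinkage formulation:
  IC = log₂((n₁₁+½)/(E+½)), and IC025 is the exact 2.5 % quantile of
  log₂ λ under the posterior λ·(E+½) ~ Gamma(n₁₁+½, 1). This modern
  formulation was chosen over the original normal-approximation BCPNN
  variant for tractability and exactness; the ½ offsets keep everything
  finite for any table, and the bound is validated against 10⁶-draw
  Monte-Carlo posterior quantiles.
- **EBGM** follows DuMouchel's MGPS model: λ has a two-component gamma
  mixture prior, n₁₁ ~ Poisson(λE) marginalizes to a two-component
  negative-binomial mixture, and the prior's five parameters
  (α₁, β₁, α₂, β₂, p) are fitted once per database by maximizing the
  marginal likelihood over all drug×event pairs (L-BFGS-B on log/logit
  scales from the canonical start (0.2, 0.1, 2.0, 4.0, ⅓), parameters
  boxed to e^±15 to keep the objective finite; an occasional line-search
  failure is polished with Nelder–Mead, and an objective plateau — e.g. a
  boundary optimum where one component degenerates toward a point mass on
  null data — counts as converged; anything else raises with best-so-far
  parameters). The posterior is the conjugate gamma mixture with
  weights ∝ prior weight × negative-binomial evidence;
  EBGM = 2^{E[log₂ λ | data]} from the exact digamma expression, and EB05
  is the posterior 5th percentile found by bracketed root-finding on the
  mixture CDF to 10⁻⁸.

A pair is a **signal** iff all four strict inequalities hold: IC025 > 0,
PRR025 > 1, ROR025 > 1, EB05 > 1. Pairs with an undefined statistic are
non-signals with a reason code. The prior is database-wide (standard MGPS
practice); stratification is not implemented — a single age stratum is
analyzed by filtering the database instead.

## Nested case-control screen

For one drug: exposed persons are eligible pregnancy episodes with at least
one prescription of the drug in [index−270, index]; their observation
window is the 60 days ("two months") from the **first** qualifying
prescription, clamped so it never passes the index day. Unexposed persons
receive a window of equal length whose start offset relative to the index
is sampled (seeded) from the empirical distribution of exposed offsets —
the design's largest inference, since nothing anchors a control's window
naturally; matching the exposed offset distribution removes the systematic
timing difference that any fixed control window would introduce. A person
is outcome-positive for an ICD-10 code if ≥ 1 diagnosis of that code falls
in their window (repeats count once). Each code's exposed × outcome table
is tested with a Pearson chi-square, 1 df, no continuity correction by
default (a flag enables it), against a fixed 10⁻⁵ p-value threshold that
serves as the multiplicity control; no FDR procedure is layered on top.
Codes matching blocklist prefixes are excluded from the new-ADE report in
fixed precedence (pregnancy-related, indication-related, label-known,
literature-known; first match wins) but retained in the full output with
their reason.

## Synthetic-data generators

The generators produce the statistical structure the analyses consume, not
facsimiles of any proprietary source; file dialects of real spontaneous-
report or claims extracts are explicitly out of scope.

**Corpus**: each record draws a relevance flag (default relevant fraction
2778/4845, the bundled labeled-corpus composition) and, if relevant, one of
the five admissible label combinations (PE, CT, PK, PK+PE, PK+CT) with
probabilities proportional to that composition. Drugs are drawn from a
zipf law over the drug list (default exponent 1.5 — a conventional
heavy-tail choice, as the marginal distribution of real per-drug paper
counts is not published); each assigned drug name is embedded verbatim in
exactly one of title/abstract/MeSH chosen uniformly (and echoed in
keywords), each assigned population tag via one of its synonyms likewise,
so lexicon scanning can recover assignments exactly. Study-type cue
phrases make the corpus linearly separable for the reference classifier —
by design, so classifier-quality failures are attributable to the harness
rather than the text model.

**Reports**: each report includes drug d with probability p (default 0.06)
and event e with probability q (default 0.08), independently per item. For
an injected pair (d, e, λ), reports containing d but not e gain e with
probability (λ−1)q/(1−q), making P(e|d) = λq exactly while P(e|¬d) = q, so
the pair's relative reporting rate is exactly λ and every 2×2 margin is
analytically predictable. Reports with no drug or no event are rejection-
resampled, which preserves independence for null pairs because the
conditioning event factorizes into a drug-only and an event-only part.
Default size 50,000 reports.

**Claims**: default 20,000 persons, a configurable pregnant fraction;
pregnant persons get one delivery event (index in the interior of a
six-year day horizon), mothers aged ≥ 24 at delivery (so they never enter
a pediatric age group in earlier study years), full-horizon enrollment
except for a configurable violator fraction (default 0.2) whose span
starts only 100 days before the index. Pregnancy-window prescriptions are
anchored uniformly in [index−270, index−60] so a full 60-day exposure
window fits before the index. Baseline diagnoses arrive with a constant
per-day hazard calibrated so that P(≥ 1 occurrence in any 60-day window)
equals the baseline rate (default 0.01) — constant hazard is what makes
the null screen symmetric between exposed and control windows. For an
injected ADE (drug, code, exposed, baseline), exposed persons gain an
extra in-window diagnosis with probability (exposed−baseline)/(1−baseline),
raising their window probability to exactly the exposed rate. Pediatric
persons get per-year prescriptions at a constant per-drug rate.

What the generators do **not** emulate: duplicate/versioned case reports,
MedDRA or ICD hierarchies, seasonal or secular trends, correlated drug
co-prescription, confounding by indication, gestational-age structure, and
realistic marginal heterogeneity across drugs and events. Passing
recovery tests therefore demonstrates the correctness of the counting,
windowing and statistical machinery under the stated model — not
robustness to the messiness of real spontaneous-report or claims data.

## Problem sizes and numerical choices

The standing test conditions are: 200-table oracle grids with reporting
ratios log-uniform in [0.2, 10] (the regime screened pairs live in, where
an absolute 0.01 Monte-Carlo tolerance is meaningful); 10 × 5000-pair MGPS
recovery fits with expected counts log-uniform in [0.5, 100] (estimates
averaged over seeds before comparison, since the heavy-tail rate parameter
is noisy in single fits; fitted components are reported low-mean-first to
resolve mixture label switching); 20 × 50,000-report signal screens with
three injected λ = 10 pairs; 20 × 20,000-person null case-control screens
over 100 codes plus one injected-ADE power run; a 3000-paper/6000-person
end-to-end landscape; and 2000-paper calibration corpora with 5 % label
noise. Ties in rankings and heatmap row orders break alphabetically;
heatmap rows are ordered by descending overall publication frequency.

## Known limitations

- The reference classifier is a linear bag-of-words model: adequate for
  the separable synthetic corpus and for exercising the evaluation
  harness, not a substitute for a domain-pretrained encoder on real text.
- The chi-square screen assumes independent persons and one stratum; no
  covariate adjustment or matching is performed.
- Control-window sampling in the case-control screen is a modeling
  decision (documented above), not an estimated quantity.
- Lexicon scanning is surface-form matching; it cannot resolve context-
  dependent ambiguity (a drug mentioned as a non-therapeutic reagent still
  counts).
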