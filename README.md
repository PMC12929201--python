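# gapvigil

Pharmacotherapy knowledge-gap landscape analysis and pharmacovigilance
screening for maternal and pediatric populations.

Pregnant and postpartum women, and children, are chronically underrepresented
in clinical pharmacology research, yet they are prescribed hundreds of
distinct drugs. `gapvigil` quantifies that mismatch and screens its most
worrying corner — highly prescribed drugs with little or no published
evidence — for adverse-event signals in real-world-style data. The package
implements the full analysis chain as a tested Python library:

1. **Literature annotation** — drug/population/disease lexicons with
   cleaning rules (synonyms under five characters are excluded, dosage
   tokens removed, cross-entry ambiguous synonyms dropped), word-boundary
   scanning of title/abstract/keywords/MeSH, and distinct-record publication
   counts per (drug, subpopulation, study type). Study types are PK
   (pharmacokinetics), PE (pharmaco-epidemiology) and CT (clinical trial);
   PE and CT are mutually exclusive, PK may co-occur with either.
2. **Triage evaluation** — stratified k-fold cross-validation of pluggable
   one-vs-non-relevant study-type classifiers over 512-token text chunks
   (max-pooled per record), misclassification *calibration* (re-review of
   flagged labels), and exact-tuple inter-annotator agreement with
   third-party adjudication.
3. **Knowledge-gap landscape** — claims-based prescription rates with the
   pregnancy windowing (index date = first delivery code; eligibility
   requires continuous enrollment over [index−270 d, index+180 d];
   pregnancy window [index−270, index−1], postpartum [index, index+180])
   and per-year pediatric age groups [0,1), [1,12), [12,18]; evidence
   classes (no evidence = 0 papers, weak < 5, adequate ≥ 5); gap relative
   frequencies; and ranking of no-evidence drugs by prescription volume.
4. **Disproportionality screening** (spontaneous reports) — PRR, ROR, the
   shrunk information component IC = log₂((n₁₁+½)/(E+½)) with its exact
   gamma-posterior 2.5th-percentile bound, and DuMouchel's MGPS
   empirical-Bayes geometric mean (EBGM) under a two-component gamma
   mixture prior fitted by maximum marginal likelihood. A pair is a signal
   iff IC025 > 0 ∧ PRR025 > 1 ∧ ROR025 > 1 ∧ EB05 > 1.
5. **Nested case-control screening** (claims) — 60-day exposure windows
   inside the pregnancy period, person-level ICD-10 outcome indicators,
   Pearson chi-square per code at a stringent 10⁻⁵ threshold, and prefix
   blocklists (pregnancy-related, indication-related, label-known,
   literature-known) that exclude codes from the new-ADE report.
6. **Synthetic data** — seeded generators for all three substrates with
   recoverable ground truth: zipf-tailed per-drug paper counts, injected
   drug–event reporting-rate multipliers λ, and injected drug–diagnosis
   rate elevations, so every downstream stage can be validated end to end.

## Worked example

```python
from gapvigil import SimConfig, gen_report_database, screen_signals

cfg = SimConfig(seed=3, n_reports=30_000,
                injected_signals=(("drugalfa", "event rash", 10.0),))
db, truth = gen_report_database(cfg)
for d in screen_signals(db):
    if d.is_signal:
        s = d.stats
        print(f"{d.drug} / {d.event}: PRR025={s.prr025:.2f} "
              f"ROR025={s.ror025:.2f} IC025={s.ic025:.2f} EB05={s.eb05:.2f}")
```

prints

```
drugalfa / event rash: PRR025=8.78 ROR025=45.91 IC025=2.21 EB05=4.66
```

The injected pair — whose co-reporting probability was multiplied by
λ = 10 — is the only one of 375 drug × event pairs whose four lower bounds
all clear their thresholds; the remaining null pairs hover near a relative
reporting rate of 1 and are shrunk further by the empirical-Bayes prior.
The `examples/` directory holds one short narrative script per capability
(simulation, annotation, landscape, disproportionality, case-control,
triage), each printing the numbers it computes and what they mean.

A thin CLI wraps the same functions:

```bash
gapvigil simulate --kind reports --seed 3 --out out/
gapvigil faers-screen --reports out/reports.jsonl --out out/
gapvigil run --seed 7 --out run/        # full pipeline with manifest
```

## Documentation

`docs/methods.md` describes the models, windowing conventions, the MGPS
fitting procedure, the synthetic-data generators' design and what they do
and do not emulate, and the package's numerical choices and limitations.
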