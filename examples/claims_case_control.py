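"""Nested case-control screen for drug-associated diagnoses in pregnancy.

Exposed persons get a 60-day window starting at their first qualifying
prescription inside the pregnancy period; controls get an equal-length
window whose offset is sampled from the exposed offsets.  Each ICD-10 code
is tested with a chi-square at the stringent 1e-5 threshold, and codes on
the configured blocklists are excluded from the new-ADE report.
"""

from gapvigil import SimConfig, gen_claims_cohort, build_pregnancy_cohort, \
    run_screen, ScreenConfig

config = SimConfig(
    seed=9, n_papers=0, n_persons=10_000, pregnancy_fraction=1.0,
    injected_ades=(("drugalfa", "K52.9", 0.10, 0.01),
                   ("drugalfa", "O26.8", 0.10, 0.01)),
)
cohort, truth = gen_claims_cohort(config)
episodes = build_pregnancy_cohort(cohort, config.delivery_codes)

results = run_screen(
    episodes, ["drugalfa"], cohort.prescriptions, cohort.diagnoses,
    ScreenConfig(window_days=60, p_threshold=1e-5, seed=9),
    codes=set(config.icd10_codes) | {"K52.9", "O26.8"},
    blocklists={"pregnancy_related": ["O"]},
)

for r in results:
    if r.passes_threshold:
        tag = r.filtered_reason or "NEW ADE candidate"
        print(f"{r.drug} / {r.icd10_code}: chi2={r.chi2:.1f} "
              f"p={r.p_value:.2e} -> {tag}")
# Both injected codes reach significance, but O26.8 is pregnancy-related and
# therefore filtered; only K52.9 remains a new-ADE candidate.
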