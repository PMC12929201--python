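"""Build a drug lexicon, scan abstracts, and count publications per drug.

Synonyms shorter than five characters are dropped before scanning (they
cause false hits), matching is word-boundary and case-insensitive, and
publication counts are distinct records, never mentions.
"""

from gapvigil import build_drug_lexicon, annotate_corpus, count_publications
from gapvigil.lexicon import AbstractRecord, default_population_lexicon

lexicon = build_drug_lexicon({
    "aspirin": ["ASA", "acetylsalicylic acid"],   # "ASA" is dropped (3 chars)
    "acetaminophen": ["paracetamol", "tylenol"],
})
print("lexicon entries:", {k: sorted(v) for k, v in lexicon.entries.items()})

records = [
    AbstractRecord("PM1", title="Acetylsalicylic acid kinetics in pregnancy",
                   abstract="Aspirin clearance was measured in pregnant women."),
    AbstractRecord("PM2", title="Supraspinatus repair outcomes",
                   abstract="No therapeutic compounds were studied."),
    AbstractRecord("PM3", title="Paracetamol exposure in infants",
                   mesh_terms=("Acetaminophen", "Infant")),
]
annotations = annotate_corpus(
    records, lexicon, default_population_lexicon(),
    study_labels={"PM1": {"PK"}, "PM3": {"PK", "PE"}})

for a in annotations:
    print(a.record_id, "drugs:", sorted(a.drugs), "pops:", sorted(a.populations))

print("\npublication counts (distinct records per drug/population/type):")
print(count_publications(annotations).to_string(index=False))
# PM2 matches nothing: "supraspinatus" does not contain "aspirin" at a word
# boundary, which is exactly why short/ambiguous synonyms are excluded.
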