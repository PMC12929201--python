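"""Drug/population/disease lexicons and abstract annotation.

Drug mentions are found by scanning title, abstract, keywords and MeSH
headings against a cleaned synonym vocabulary: synonyms are case-folded,
whitespace-normalized, synonyms shorter than five characters are excluded
(short strings are too ambiguous to scan safely), dosage-like tokens are
removed, and synonyms shared by several canonical drugs are dropped from all
of them.  Matching is word-boundary, case-insensitive and
longest-synonym-first, so "supraspinatus" never matches "aspirin".

Population tags come from a closed list of maternal and pediatric
subpopulations; diseases are MeSH terms restricted to the C (Diseases) and
F (Psychiatry and Psychology) branches of the MeSH tree.  Study-type labels
(PK/PE/CT) are classifier outputs supplied from outside and only validated
here: PE and CT are mutually exclusive, PK may accompany either.

Publication frequencies count distinct records, never mentions.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "STUDY_TYPES",
    "POPULATION_TAGS",
    "AbstractRecord",
    "DrugLexicon",
    "PopulationLexicon",
    "DiseaseTaxonomy",
    "AnnotationResult",
    "build_drug_lexicon",
    "clean_claims_drug_name",
    "annotate_record",
    "count_publications",
    "validate_study_labels",
]

STUDY_TYPES = ("PK", "PE", "CT")

POPULATION_TAGS = (
    "pregnancy", "labor_delivery", "lactation", "postpartum", "mother",
    "preterm", "neonate", "newborn", "infant", "children", "adolescent",
    "fetus", "pediatric",
)

MIN_SYNONYM_LEN = 5

#: a number glued to a unit, e.g. "500 mg", "0.5%", "10ml/kg"
_DOSAGE_RE = re.compile(r"\d+(\.\d+)?\s*(mg|mcg|ug|g|ml|l|iu|%)(/\w+)?\b", re.I)


@dataclass(frozen=True)
class AbstractRecord:
    """One literature record with the fields used for scanning."""

    record_id: str
    title: str = ""
    abstract: str = ""
    mesh_terms: tuple[str, ...] = ()
    keywords: tuple[str, ...] = ()
    year: int = 0
    language: str = "eng"


def _normalize(s: str) -> str:
    s = unicodedata.normalize("NFKC", s).casefold()
    return " ".join(s.split())


@dataclass
class DrugLexicon:
    """Canonical drug names mapped to cleaned synonym sets (case-folded)."""

    entries: dict[str, frozenset] = field(default_factory=dict)
    provenance: str = ""
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for name, syns in self.entries.items():
            for s in syns:
                if len(s) < MIN_SYNONYM_LEN:
                    raise ValueError(f"synonym {s!r} shorter than {MIN_SYNONYM_LEN} chars")
                if s in seen and seen[s] != name:
                    raise ValueError(f"synonym {s!r} shared by {seen[s]!r} and {name!r}")
                seen[s] = name

    def to_json(self) -> str:
        payload = {k: sorted(v) for k, v in sorted(self.entries.items())}
        return json.dumps({"provenance": self.provenance, "entries": payload}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DrugLexicon":
        obj = json.loads(text)
        return cls({k: frozenset(v) for k, v in obj["entries"].items()},
                   provenance=obj.get("provenance", ""))

    def to_tsv(self) -> str:
        lines = ["canonical\tsynonym"]
        for name in sorted(self.entries):
            for syn in sorted(self.entries[name]):
                lines.append(f"{name}\t{syn}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "DrugLexicon":
        entries: dict[str, set] = {}
        for i, line in enumerate(text.splitlines()):
            if not line.strip() or (i == 0 and line.startswith("canonical")):
                continue
            name, syn = line.split("\t")
            entries.setdefault(name, set()).add(syn)
        return cls({k: frozenset(v) for k, v in entries.items()})


def build_drug_lexicon(
    raw_synonym_lists: Mapping[str, Sequence[str]], provenance: str = ""
) -> DrugLexicon:
    """Clean raw synonym lists into a scanning vocabulary.

    Cleaning: case-fold and whitespace-normalize; always include the
    canonical name itself as a candidate synonym; drop synonyms under five
    characters and dosage-like tokens; drop any synonym that survives in two
    or more entries (ambiguous) from all of them.  An entry whose synonym set
    empties out is kept if its canonical name is itself a valid synonym,
    otherwise it lands in ``dropped``.
    """
    cleaned: dict[str, set] = {}
    for name, syns in raw_synonym_lists.items():
        if not syns and not name:
            raise ValueError("empty synonym list with empty canonical name")
        canon = _normalize(name)
        out = set()
        for raw in list(syns) + [name]:
            s = _normalize(raw)
            if len(s) < MIN_SYNONYM_LEN:
                continue
            if _DOSAGE_RE.search(s):
                continue
            out.add(s)
        cleaned[canon] = out
    # cross-entry ambiguity: a synonym in >1 entry is dropped everywhere
    counts: dict[str, int] = {}
    for syns in cleaned.values():
        for s in syns:
            counts[s] = counts.get(s, 0) + 1
    ambiguous = {s for s, c in counts.items() if c > 1}
    entries = {}
    dropped = []
    for name, syns in cleaned.items():
        keep = frozenset(syns - ambiguous)
        if keep:
            entries[name] = keep
        else:
            dropped.append(name)
    return DrugLexicon(entries, provenance=provenance, dropped=tuple(sorted(dropped)))


@dataclass
class PopulationLexicon:
    """Closed-tag population vocabulary (tag -> synonym set)."""

    entries: dict[str, frozenset]

    def __post_init__(self) -> None:
        bad = set(self.entries) - set(POPULATION_TAGS)
        if bad:
            raise ValueError(f"unknown population tags: {sorted(bad)}")


#: compact default population synonyms (a stand-in for a full curated list)
DEFAULT_POPULATION_SYNONYMS: dict[str, tuple[str, ...]] = {
    "pregnancy": ("pregnancy", "pregnant", "gestation", "prenatal", "antenatal"),
    "labor_delivery": ("labor", "labour", "delivery", "childbirth", "intrapartum",
                       "cesarean", "caesarean"),
    "lactation": ("lactation", "breastfeeding", "breast milk", "breast-feeding",
                  "nursing mothers"),
    "postpartum": ("postpartum", "post-partum", "puerperium", "puerperal"),
    "mother": ("mother", "mothers", "maternal"),
    "preterm": ("preterm", "premature infant", "prematurity"),
    "neonate": ("neonate", "neonates", "neonatal"),
    "newborn": ("newborn", "newborns"),
    "infant": ("infant", "infants", "infancy"),
    "children": ("child", "children", "childhood"),
    "adolescent": ("adolescent", "adolescents", "adolescence", "teenager", "teenagers"),
    "fetus": ("fetus", "fetal", "foetus", "foetal"),
    "pediatric": ("pediatric", "paediatric", "pediatrics", "paediatrics"),
}


def default_population_lexicon() -> PopulationLexicon:
    return PopulationLexicon(
        {k: frozenset(_normalize(s) for s in v)
         for k, v in DEFAULT_POPULATION_SYNONYMS.items()}
    )


@dataclass
class DiseaseTaxonomy:
    """MeSH terms restricted to disease branches of the tree (C and F)."""

    term_to_tree: dict[str, tuple[str, ...]]
    mesh_tree_prefixes: frozenset = frozenset({"C", "F"})

    def __post_init__(self) -> None:
        for term, codes in self.term_to_tree.items():
            if not any(c.startswith(tuple(self.mesh_tree_prefixes)) for c in codes):
                raise ValueError(
                    f"term {term!r} has no tree code under {sorted(self.mesh_tree_prefixes)}"
                )
        self._terms = {_normalize(t) for t in self.term_to_tree}

    def contains(self, term: str) -> bool:
        return _normalize(term) in self._terms


@dataclass(frozen=True)
class AnnotationResult:
    record_id: str
    drugs: frozenset
    populations: frozenset
    diseases: frozenset
    study_types: frozenset

    def __post_init__(self) -> None:
        validate_study_labels(self.study_types)


def validate_study_labels(labels: Iterable[str]) -> frozenset:
    """Enforce the label model: PE and CT never co-occur; PK is free."""
    labels = frozenset(labels)
    unknown = labels - set(STUDY_TYPES)
    if unknown:
        raise ValueError(f"unknown study types: {sorted(unknown)}")
    if {"PE", "CT"} <= labels:
        raise ValueError("PE and CT are mutually exclusive")
    return labels


class _Scanner:
    """Word-boundary, case-insensitive, longest-first multi-term matcher."""

    def __init__(self, term_to_key: Mapping[str, str]):
        # longest-first so overlapping synonyms resolve to the longest match
        terms = sorted(term_to_key, key=len, reverse=True)
        self._key = dict(term_to_key)
        if terms:
            pat = "|".join(re.escape(t) for t in terms)
            self._re = re.compile(rf"(?<!\w)({pat})(?!\w)")
        else:
            self._re = None

    def scan(self, text: str) -> set:
        if self._re is None or not text:
            return set()
        return {self._key[m.group(1)] for m in self._re.finditer(_normalize(text))}


def drug_scanner(lex: DrugLexicon) -> _Scanner:
    return _Scanner({s: name for name, syns in lex.entries.items() for s in syns})


def population_scanner(lex: PopulationLexicon) -> _Scanner:
    return _Scanner({s: tag for tag, syns in lex.entries.items() for s in syns})


def annotate_record(
    record: AbstractRecord,
    drug_lex: DrugLexicon,
    pop_lex: PopulationLexicon,
    disease_tax: DiseaseTaxonomy | None = None,
    study_labels: Iterable[str] | None = None,
    _scanners: tuple[_Scanner, _Scanner] | None = None,
) -> AnnotationResult:
    """Annotate one record with drugs, populations, diseases and study types.

    Drugs are scanned over title, abstract, keywords and MeSH; populations
    over title, abstract and MeSH only (keywords are not scanned for
    populations); diseases are the MeSH terms present in the taxonomy; study
    types are copied from ``study_labels`` unchanged after validation.
    """
    dscan, pscan = _scanners if _scanners else (drug_scanner(drug_lex),
                                                population_scanner(pop_lex))
    drug_text = " \n ".join(
        [record.title, record.abstract, " \n ".join(record.keywords),
         " \n ".join(record.mesh_terms)]
    )
    pop_text = " \n ".join(
        [record.title, record.abstract, " \n ".join(record.mesh_terms)]
    )
    drugs = dscan.scan(drug_text)
    pops = pscan.scan(pop_text)
    diseases: set = set()
    if disease_tax is not None:
        diseases = {t for t in record.mesh_terms if disease_tax.contains(t)}
    labels = validate_study_labels(study_labels or ())
    return AnnotationResult(record.record_id, frozenset(drugs), frozenset(pops),
                            frozenset(diseases), labels)


def annotate_corpus(
    records: Sequence[AbstractRecord],
    drug_lex: DrugLexicon,
    pop_lex: PopulationLexicon,
    disease_tax: DiseaseTaxonomy | None = None,
    study_labels: Mapping[str, Iterable[str]] | None = None,
) -> list[AnnotationResult]:
    """Annotate many records, building each scanner once."""
    scanners = (drug_scanner(drug_lex), population_scanner(pop_lex))
    study_labels = study_labels or {}
    return [
        annotate_record(r, drug_lex, pop_lex, disease_tax,
                        study_labels.get(r.record_id, ()), _scanners=scanners)
        for r in records
    ]


def count_publications(annotations: Sequence[AnnotationResult]) -> pd.DataFrame:
    """Distinct-record publication counts per (drug, population, study type).

    A record with d drugs, p populations and s study types contributes one
    count to each of the d*p*s cells; re-annotating or reordering the corpus
    cannot change the result.
    """
    ids = [a.record_id for a in annotations]
    if len(ids) != len(set(ids)):
        raise ValueError("record ids must be unique")
    rows = []
    for a in annotations:
        for drug in a.drugs:
            for pop in a.populations:
                for st in a.study_types:
                    rows.append((drug, pop, st))
    df = pd.DataFrame(rows, columns=["drug", "population", "study_type"])
    out = (
        df.groupby(["drug", "population", "study_type"], as_index=False)
        .size()
        .rename(columns={"size": "paper_count"})
        .sort_values(["drug", "population", "study_type"], ignore_index=True)
    )
    return out


def annotations_to_tables(annotations: Sequence[AnnotationResult]) -> dict[str, pd.DataFrame]:
    """Relational export: pmid2drug, pmid2pop, pmid2disease, pmid2studytype."""
    def table(attr: str, col: str) -> pd.DataFrame:
        rows = [(a.record_id, v) for a in annotations for v in sorted(getattr(a, attr))]
        return pd.DataFrame(rows, columns=["pmid", col]).sort_values(
            ["pmid", col], ignore_index=True)

    return {
        "pmid2drug": table("drugs", "drug"),
        "pmid2pop": table("populations", "population"),
        "pmid2disease": table("diseases", "disease"),
        "pmid2studytype": table("study_types", "study_type"),
    }


# ---------------------------------------------------------------------------
# claims drug-name normalization
# ---------------------------------------------------------------------------

MULTI_INGREDIENT_DELIMITERS = ("-", "/", ";", " with ", " and ")

#: whole-name categories removed outright (allergens, vaccines, kits, ...)
DEFAULT_CATEGORY_TERMS = (
    "allergen", "allergenic", "extract", "vaccine", "prenatal vitamin",
    "prenatal vitamins", "lotion", "kit",
)

#: source organisms stripped from names
DEFAULT_SOURCE_TERMS = ("human", "bovine", "porcine", "recombinant", "synthetic")

#: manufacturing / molecular-modification descriptors stripped from names
DEFAULT_PROCESS_TERMS = (
    "micronized", "micronised", "injection", "injectable", "pegylated",
    "liposomal", "extended release", "delayed release", "topical", "oral",
    "solution", "suspension", "cream", "ointment", "tablet", "capsule",
)

#: salt / formulation suffixes stripped from names
DEFAULT_SALT_TERMS = (
    "hydrochloride", "hcl", "sodium", "calcium", "potassium", "magnesium",
    "sulfate", "sulphate", "phosphate", "acetate", "tartrate", "citrate",
    "maleate", "mesylate", "besylate", "succinate", "fumarate", "bromide",
    "chloride", "nitrate", "dihydrate", "monohydrate", "benzoate",
)


@dataclass(frozen=True)
class ClaimsNameFilter:
    category_terms: tuple[str, ...] = DEFAULT_CATEGORY_TERMS
    source_terms: tuple[str, ...] = DEFAULT_SOURCE_TERMS
    process_terms: tuple[str, ...] = DEFAULT_PROCESS_TERMS
    salt_terms: tuple[str, ...] = DEFAULT_SALT_TERMS


def clean_claims_drug_name(
    raw_name: str, filter_vocab: ClaimsNameFilter | None = None
) -> list[str]:
    """Normalize a claims drug name to canonical ingredient names.

    Multi-ingredient names split on the configured delimiters; ingredients in
    the removed categories (allergens, extracts, vaccines, prenatal vitamins,
    lotions, kits) vanish; source, process and salt/formulation terms are
    stripped token-wise.  Unmatched names pass through lowercased.  The result
    may be empty and preserves first-occurrence order without duplicates.
    """
    if not raw_name or not raw_name.strip():
        raise ValueError("raw drug name must be nonempty")
    fv = filter_vocab or ClaimsNameFilter()
    name = _normalize(raw_name)
    parts = [name]
    for delim in MULTI_INGREDIENT_DELIMITERS:
        parts = [p for chunk in parts for p in chunk.split(delim)]
    out: list[str] = []
    strip_terms = set(fv.source_terms) | set(fv.process_terms) | set(fv.salt_terms)
    for part in parts:
        part = part.strip()
        if not part:
            continue
        if any(term in part for term in fv.category_terms):
            continue
        tokens = [t for t in part.split() if t not in strip_terms]
        cleaned = " ".join(tokens)
        if cleaned and cleaned not in out:
            out.append(cleaned)
    return out
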