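"""Claims-based prescription rates, knowledge-gap classification and ranking.

The pregnancy cohort is anchored on the index date — the day of a person's
first delivery procedure code.  Persons must be continuously enrolled from
270 days before to 180 days after the index date to be eligible.
Prescriptions in [index-270, index-1] count toward the pregnancy
subpopulation and prescriptions in [index, index+180] toward postpartum, so
the two windows partition [index-270, index+180].

Pediatric rates use three age groups with half-open intervals — [0, 1),
[1, 12), [12, 18] years — assigned per person-year; sample sizes are
cumulative across the observed years.

A drug's literature evidence for a (subpopulation, study-type) cell is
classified from its publication count: no evidence (0 papers), weak evidence
(1-4 papers), adequate (>= 5).  The knowledge gap of a cell is the relative
frequency of prescribed drugs with no or weak evidence.  Drugs with zero
papers across all study types are ranked by prescription count for
follow-up pharmacovigilance.

All dates are integer day numbers relative to an arbitrary epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lexicon import STUDY_TYPES

__all__ = [
    "SUBPOPULATIONS",
    "PEDIATRIC_GROUPS",
    "ClaimsCohort",
    "PregnancyEpisode",
    "EvidenceClass",
    "GapSummary",
    "build_pregnancy_cohort",
    "window_prescription_counts",
    "pregnancy_postpartum_rates",
    "pediatric_rates",
    "filter_min_prescriptions",
    "classify_evidence",
    "gap_summary",
    "rank_no_evidence",
    "miss_probability",
]

SUBPOPULATIONS = ("pregnancy", "postpartum", "ped_0_1", "ped_1_12", "ped_12_18")

#: pediatric age groups in years: [lo, hi) except the last, closed at 18
PEDIATRIC_GROUPS = (("ped_0_1", 0.0, 1.0), ("ped_1_12", 1.0, 12.0),
                    ("ped_12_18", 12.0, 18.0))

PREGNANCY_LOOKBACK_DAYS = 270
POSTPARTUM_FOLLOWUP_DAYS = 180
WEAK_EVIDENCE_CUTOFF = 5
MIN_PRESCRIPTIONS = 10
DAYS_PER_YEAR = 365.0


@dataclass
class ClaimsCohort:
    """Claims-like tables: persons, enrollment, prescriptions, diagnoses,
    delivery events.  All day columns are integer days from a common epoch."""

    persons: pd.DataFrame          # person_id, birth_day, sex
    enrollment_spans: pd.DataFrame  # person_id, start_day, end_day
    prescriptions: pd.DataFrame    # person_id, drug, day
    diagnoses: pd.DataFrame        # person_id, icd10_code, day
    delivery_events: pd.DataFrame  # person_id, day, code

    def __post_init__(self) -> None:
        spans = self.enrollment_spans
        if len(spans) and (spans["start_day"] > spans["end_day"]).any():
            raise ValueError("enrollment spans must have start_day <= end_day")
        known = set(self.persons["person_id"])
        for name in ("enrollment_spans", "prescriptions", "diagnoses", "delivery_events"):
            df = getattr(self, name)
            if len(df) and not set(df["person_id"]).issubset(known):
                raise ValueError(f"{name} references unknown persons")


@dataclass(frozen=True)
class PregnancyEpisode:
    person_id: object
    index_day: int
    eligible: bool


def build_pregnancy_cohort(
    claims: ClaimsCohort, delivery_codes: Sequence[str] | None = None
) -> list[PregnancyEpisode]:
    """One episode per person with a delivery code; index = first such day.

    Eligibility requires enrollment spans covering the whole interval
    [index-270, index+180] without a gap (adjacent/overlapping spans merge).
    """
    ev = claims.delivery_events
    if delivery_codes is not None:
        if not len(delivery_codes):
            raise ValueError("delivery_codes must be nonempty")
        ev = ev[ev["code"].isin(set(delivery_codes))]
    if not len(ev):
        return []
    index_days = ev.groupby("person_id")["day"].min()
    spans_by_person = dict(tuple(claims.enrollment_spans.groupby("person_id")))
    episodes = []
    for person_id, index_day in index_days.items():
        lo = index_day - PREGNANCY_LOOKBACK_DAYS
        hi = index_day + POSTPARTUM_FOLLOWUP_DAYS
        spans = spans_by_person.get(person_id)
        episodes.append(
            PregnancyEpisode(person_id, int(index_day),
                             _covers(spans, lo, hi) if spans is not None else False)
        )
    episodes.sort(key=lambda e: str(e.person_id))
    return episodes


def _covers(spans: pd.DataFrame, lo: int, hi: int) -> bool:
    """True iff the union of [start, end] spans covers [lo, hi] gaplessly."""
    ivals = sorted(zip(spans["start_day"], spans["end_day"]))
    cursor = lo
    for start, end in ivals:
        if start > cursor:
            break
        cursor = max(cursor, end + 1)
        if cursor > hi:
            return True
    return cursor > hi


def window_prescription_counts(
    episodes: Iterable[PregnancyEpisode],
    prescriptions: pd.DataFrame,
    distinct_persons: bool = False,
) -> pd.DataFrame:
    """Per-drug prescription counts in the pregnancy and postpartum windows.

    Pregnancy window: [index-270, index-1]; postpartum: [index, index+180].
    Each fill counts once (event-level); ``distinct_persons`` switches to
    person-level counting.  Only eligible episodes contribute.
    """
    eligible = {e.person_id: e.index_day for e in episodes if e.eligible}
    df = prescriptions[prescriptions["person_id"].isin(eligible)].copy()
    if not len(df):
        return pd.DataFrame(columns=["subpopulation", "drug", "n_prescriptions"])
    df["rel"] = df["day"] - df["person_id"].map(eligible)
    df["subpopulation"] = np.select(
        [(df["rel"] >= -PREGNANCY_LOOKBACK_DAYS) & (df["rel"] <= -1),
         (df["rel"] >= 0) & (df["rel"] <= POSTPARTUM_FOLLOWUP_DAYS)],
        ["pregnancy", "postpartum"], default="",
    )
    df = df[df["subpopulation"] != ""]
    if distinct_persons:
        df = df.drop_duplicates(["subpopulation", "drug", "person_id"])
    out = (
        df.groupby(["subpopulation", "drug"], as_index=False).size()
        .rename(columns={"size": "n_prescriptions"})
        .sort_values(["subpopulation", "drug"], ignore_index=True)
    )
    return out


def pregnancy_postpartum_rates(
    episodes: Iterable[PregnancyEpisode],
    prescriptions: pd.DataFrame,
    distinct_persons: bool = False,
) -> pd.DataFrame:
    """Rate table rows for the pregnancy and postpartum subpopulations.

    The sample size of both subpopulations is the number of eligible
    episodes; rate = n_prescriptions / sample_size (also given per 1000).
    """
    episodes = list(episodes)
    n_eligible = sum(e.eligible for e in episodes)
    counts = window_prescription_counts(episodes, prescriptions, distinct_persons)
    if n_eligible == 0:
        if len(counts):
            raise ValueError("no eligible episodes")
        return _finish_rates(counts.assign(sample_size=pd.Series(dtype=int)))
    counts["sample_size"] = n_eligible
    return _finish_rates(counts)


def _finish_rates(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["rate"] = df["n_prescriptions"] / df["sample_size"]
    df["rate_per_1000"] = 1000.0 * df["rate"]
    return df


def _age_years(day, birth_day) -> float:
    return (day - birth_day) / DAYS_PER_YEAR


def age_group_of(age_years: float) -> str | None:
    """Half-open group assignment; the last group is closed at 18."""
    if age_years < 0:
        return None
    for name, lo, hi in PEDIATRIC_GROUPS:
        if lo <= age_years < hi:
            return name
    if age_years == PEDIATRIC_GROUPS[-1][2]:
        return PEDIATRIC_GROUPS[-1][0]
    return None


def pediatric_rates(
    claims: ClaimsCohort,
    years: Sequence[tuple[int, int]],
    distinct_persons: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Pediatric prescription-rate rows over a list of (start_day, end_day) years.

    A person contributes to a group's sample size in each year in which their
    mid-year age falls in the group (sample sizes are cumulative over years).
    Each prescription is assigned by the age on its own day.  Returns the rate
    table and the number of events skipped for negative age.
    """
    persons = claims.persons.set_index("person_id")["birth_day"]
    sample = {g[0]: 0 for g in PEDIATRIC_GROUPS}
    for start, end in years:
        mid = (start + end) // 2
        ages = _age_years(mid, persons.values)
        for name, lo, hi in PEDIATRIC_GROUPS:
            in_group = (ages >= lo) & (ages < hi)
            if hi == PEDIATRIC_GROUPS[-1][2]:
                in_group |= ages == hi
            sample[name] += int(np.sum(in_group))
    df = claims.prescriptions.copy()
    year_sel = np.zeros(len(df), dtype=bool)
    for start, end in years:
        year_sel |= (df["day"].values >= start) & (df["day"].values <= end)
    df = df[year_sel]
    df["age"] = _age_years(df["day"], df["person_id"].map(persons))
    n_negative = int((df["age"] < 0).sum())
    df = df[df["age"] >= 0]
    df["subpopulation"] = df["age"].map(age_group_of)
    df = df.dropna(subset=["subpopulation"])
    if distinct_persons:
        df = df.drop_duplicates(["subpopulation", "drug", "person_id"])
    out = (
        df.groupby(["subpopulation", "drug"], as_index=False).size()
        .rename(columns={"size": "n_prescriptions"})
    )
    out["sample_size"] = out["subpopulation"].map(sample)
    out = out[out["sample_size"] > 0]
    return (_finish_rates(out).sort_values(["subpopulation", "drug"],
                                           ignore_index=True), n_negative)


def filter_min_prescriptions(
    table: pd.DataFrame, threshold: int = MIN_PRESCRIPTIONS
) -> pd.DataFrame:
    """Keep rows with strictly more than ``threshold`` prescriptions."""
    if not len(table):
        return table
    return table[table["n_prescriptions"] > threshold].reset_index(drop=True)


# ---------------------------------------------------------------------------
# evidence classification and gap summary
# ---------------------------------------------------------------------------

EvidenceClass = str  # one of NO_EVIDENCE, WEAK_EVIDENCE, ADEQUATE

NO_EVIDENCE = "no_evidence"
WEAK_EVIDENCE = "weak_evidence"
ADEQUATE = "adequate"


def classify_evidence(paper_count: int) -> EvidenceClass:
    """0 papers -> no evidence; 1-4 -> weak; >=5 -> adequate."""
    if paper_count < 0:
        raise ValueError("paper count must be nonnegative")
    if paper_count == 0:
        return NO_EVIDENCE
    if paper_count < WEAK_EVIDENCE_CUTOFF:
        return WEAK_EVIDENCE
    return ADEQUATE


@dataclass(frozen=True)
class GapSummary:
    """Per (subpopulation, study type) gap cells."""

    cells: pd.DataFrame = field(repr=False)
    # columns: subpopulation, study_type, n_drugs_total, n_no_evidence,
    #          n_weak, n_adequate, relative_frequency

    def cell(self, subpopulation: str, study_type: str) -> pd.Series:
        df = self.cells
        m = (df["subpopulation"] == subpopulation) & (df["study_type"] == study_type)
        return df[m].iloc[0]


def _publication_lookup(publication_table: pd.DataFrame) -> pd.DataFrame:
    """Counts per (drug, population, study_type); records absent -> 0 later."""
    required = {"drug", "population", "study_type", "paper_count"}
    missing = required - set(publication_table.columns)
    if missing:
        raise ValueError(f"publication table missing columns: {sorted(missing)}")
    return publication_table


#: claims subpopulation -> literature population tag carrying its evidence
SUBPOP_TO_POPULATION = {
    "pregnancy": "pregnancy",
    "postpartum": "postpartum",
    "ped_0_1": "infant",
    "ped_1_12": "children",
    "ped_12_18": "adolescent",
}


def drug_paper_counts(
    publication_table: pd.DataFrame, subpopulation: str
) -> pd.Series:
    """Per-drug x study-type paper counts for one claims subpopulation."""
    pub = _publication_lookup(publication_table)
    tag = SUBPOP_TO_POPULATION.get(subpopulation, subpopulation)
    sub = pub[pub["population"] == tag]
    return sub.groupby(["drug", "study_type"])["paper_count"].sum()


def gap_summary(
    rate_table: pd.DataFrame, publication_table: pd.DataFrame
) -> GapSummary:
    """Knowledge-gap summary over the prescribed-drug universe.

    For each (subpopulation, study type): the drug universe is the drugs in
    the rate table for that subpopulation; a drug absent from the publication
    table has 0 papers; relative_frequency = (no evidence + weak) / total.
    """
    rows = []
    for subpop, sub in rate_table.groupby("subpopulation"):
        drugs = sorted(sub["drug"].unique())
        if not drugs:
            raise ValueError(f"empty drug universe for {subpop}")
        counts = drug_paper_counts(publication_table, subpop)
        for st in STUDY_TYPES:
            classes = [
                classify_evidence(int(counts.get((d, st), 0))) for d in drugs
            ]
            n_no = classes.count(NO_EVIDENCE)
            n_weak = classes.count(WEAK_EVIDENCE)
            n_total = len(drugs)
            rows.append(
                (subpop, st, n_total, n_no, n_weak, n_total - n_no - n_weak,
                 (n_no + n_weak) / n_total)
            )
    if not rows:
        raise ValueError("empty drug universe")
    cells = pd.DataFrame(
        rows, columns=["subpopulation", "study_type", "n_drugs_total",
                       "n_no_evidence", "n_weak", "n_adequate",
                       "relative_frequency"],
    ).sort_values(["subpopulation", "study_type"], ignore_index=True)
    return GapSummary(cells)


def rank_no_evidence(
    rate_table: pd.DataFrame,
    publication_table: pd.DataFrame,
    subpopulation: str,
) -> list[str]:
    """Drugs with zero papers in every study type, by prescriptions desc.

    Ties break lexicographically on the drug name.
    """
    sub = rate_table[rate_table["subpopulation"] == subpopulation]
    counts = drug_paper_counts(publication_table, subpopulation)
    totals = counts.groupby("drug").sum() if len(counts) else pd.Series(dtype=int)
    ranked = []
    for _, row in sub.iterrows():
        if int(totals.get(row["drug"], 0)) == 0:
            ranked.append((row["drug"], row["n_prescriptions"]))
    ranked.sort(key=lambda t: (-t[1], t[0]))
    return [d for d, _ in ranked]


def miss_probability(recall: float, n_papers: int) -> float:
    """Probability (in percent) that an independent per-paper classifier
    misses every one of ``n_papers`` papers: (1 - recall)**n_papers * 100.

    With recall 0.93 and the four papers of a weak-evidence drug this is
    0.07**4 = 0.0024%, the bound on overlooking weak evidence entirely.
    """
    if not 0.0 <= recall <= 1.0:
        raise ValueError("recall must lie in [0, 1]")
    if n_papers < 0:
        raise ValueError("n_papers must be nonnegative")
    return (1.0 - recall) ** n_papers * 100.0


def format_miss_probability(recall: float, n_papers: int, sig: int = 2) -> str:
    """Human-readable percentage with ``sig`` significant digits."""
    value = miss_probability(recall, n_papers)
    if value == 0:
        return "0%"
    exponent = math.floor(math.log10(abs(value)))
    rounded = round(value, -exponent + (sig - 1))
    if rounded == int(rounded):
        return f"{int(rounded)}%"
    return f"{rounded:.{max(0, -exponent + (sig - 1))}f}%"
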