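"""Seeded synthetic-data generators with recoverable ground truth.

Three generators emulate the statistical structure of the pipeline's three
real-world substrates:

* an abstract corpus — heavy-tailed per-drug publication counts (zipf-like
  rank-frequency law), study-type labels respecting the PE/CT exclusivity
  rule, drug names and population synonyms embedded verbatim in the
  title/abstract/MeSH fields so that lexicon scanning can recover them;
* a spontaneous-report database — per-report drug and event sets drawn
  independently per item, with injected drug-event pairs whose co-reporting
  probability is multiplied by a relative reporting rate lambda (so the
  empirical relative risk of an injected pair is exactly lambda in
  expectation);
* a claims cohort — pregnancy episodes with a delivery index date, a
  270-day lookback / 180-day follow-up enrollment requirement that a
  configurable fraction of persons violates, windowed prescriptions and
  ICD-10-coded diagnoses, pediatric persons with per-year ages, and injected
  drug-diagnosis adverse-event pairs that elevate the within-exposure-window
  diagnosis probability from a baseline rate to an exposed rate.

Identical configurations (same seed) produce bit-identical outputs.  Every
generated prescription and diagnosis belongs to a generated person, and every
report draws its drugs and events from the configured vocabularies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .lexicon import (
    DEFAULT_POPULATION_SYNONYMS,
    POPULATION_TAGS,
    AbstractRecord,
)
from .disproportionality import ReportDatabase
from .landscape import ClaimsCohort, age_group_of, PEDIATRIC_GROUPS
from .reference import LABELED_CORPUS_COMPOSITION, NON_RELEVANT_COUNT

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigurationError",
    "gen_abstract_corpus",
    "gen_report_database",
    "gen_claims_cohort",
    "DEFAULT_DRUGS",
    "DEFAULT_EVENTS",
    "DEFAULT_DELIVERY_CODES",
]


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


#: synthetic canonical drug names (all >= 5 characters, lexicon-safe)
DEFAULT_DRUGS = tuple(
    f"drug{w}" for w in (
        "alfa", "beta", "gama", "delt", "epsi", "zeta", "etaa", "thet",
        "iota", "kapa", "lamb", "muon", "nuon", "xiom", "omic",
    )
)

#: synthetic adverse-event preferred terms
DEFAULT_EVENTS = tuple(
    f"event {w}" for w in (
        "rash", "fever", "nausea", "vomiting", "seizure", "headache",
        "dizziness", "fatigue", "insomnia", "tremor", "pruritus", "dyspnea",
        "cough", "diarrhea", "edema", "anemia", "arrhythmia", "hypotension",
        "hypertension", "tachycardia", "bradycardia", "somnolence",
        "agitation", "anorexia", "myalgia",
    )
)

#: stand-in delivery procedure/diagnosis codes
DEFAULT_DELIVERY_CODES = ("59400", "59510", "O80", "Z37.0")

#: default ICD-10-like symptom codes for the claims generator
DEFAULT_ICD10_CODES = tuple(f"R{i:02d}.{i % 10}" for i in range(100))

_STUDY_COMBOS = tuple(sorted(LABELED_CORPUS_COMPOSITION, key=sorted))
_REL_TOTAL = sum(LABELED_CORPUS_COMPOSITION.values())
_RELEVANT_FRACTION = _REL_TOTAL / (_REL_TOTAL + NON_RELEVANT_COUNT)

#: study-type cue phrases embedded in abstracts (classifier separability);
#: deliberately free of population synonyms and drug names
_CUES = {
    "PK": "pharmacokinetic profile clearance halflife exposure concentration",
    "PE": "observational cohort registry surveillance realworld utilization",
    "CT": "randomized controlled doubleblind placebo arm enrollment",
}
_FILLER = (
    "the measurements were collected and compared across scheduled visits "
    "with standard procedures and the findings were summarized in tables"
)
_IRRELEVANT = (
    "surgical technique refinement and imaging workflow ergonomics were "
    "reviewed without therapeutic compounds"
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration shared by the three generators.

    Defaults define the package's standing study conditions: a labeled-corpus
    sized literature sample whose study-type mixture follows the bundled
    reference composition, a 50,000-report spontaneous-report database, and a
    20,000-person claims cohort.
    """

    seed: int = 0
    n_papers: int = 4845
    n_reports: int = 50_000
    n_persons: int = 20_000
    drug_names: tuple[str, ...] = DEFAULT_DRUGS
    event_names: tuple[str, ...] = DEFAULT_EVENTS
    #: ("zipf", exponent): per-drug paper counts follow rank**(-exponent)
    publication_count_law: tuple = ("zipf", 1.5)
    #: (drug, event, lambda >= 1) relative-reporting boosts
    injected_signals: tuple = ()
    #: (drug, icd10_code, exposed_rate, baseline_rate) claims ADE boosts
    injected_ades: tuple = ()
    pregnancy_fraction: float = 0.5
    # corpus knobs
    relevant_fraction: float = _RELEVANT_FRACTION
    multi_drug_prob: float = 0.25
    # report-database knobs (per-item inclusion probabilities)
    report_drug_prob: float = 0.06
    report_event_prob: float = 0.08
    # claims knobs
    enrollment_violation_fraction: float = 0.2
    pregnancy_use_rate: float = 0.15
    postpartum_use_rate: float = 0.10
    pediatric_use_rate: float = 0.05
    diagnosis_baseline_rate: float = 0.01
    exposure_window_days: int = 60
    icd10_codes: tuple[str, ...] = DEFAULT_ICD10_CODES
    delivery_codes: tuple[str, ...] = DEFAULT_DELIVERY_CODES
    n_years: int = 6

    def __post_init__(self) -> None:
        if min(self.n_papers, self.n_reports, self.n_persons) < 0:
            raise ConfigurationError("counts must be nonnegative")
        law = self.publication_count_law
        if (len(law) != 2 or law[0] != "zipf"
                or not np.isfinite(law[1]) or law[1] < 0):
            raise ConfigurationError(f"invalid publication count law: {law!r}")
        for d, e, lam in self.injected_signals:
            if lam < 1:
                raise ConfigurationError(f"lambda must be >= 1 for ({d}, {e})")
            if d not in self.drug_names or e not in self.event_names:
                raise ConfigurationError(f"injected pair ({d}, {e}) not in vocabularies")
        for d, c, er, br in self.injected_ades:
            if not (0 <= br <= er <= 1):
                raise ConfigurationError(
                    f"injected ADE ({d}, {c}) needs 0 <= baseline <= exposed <= 1")
            if d not in self.drug_names:
                raise ConfigurationError(f"injected ADE drug {d!r} not in drug_names")
        for name in ("pregnancy_fraction", "relevant_fraction", "multi_drug_prob",
                     "report_drug_prob", "report_event_prob",
                     "enrollment_violation_fraction", "pregnancy_use_rate",
                     "postpartum_use_rate", "pediatric_use_rate",
                     "diagnosis_baseline_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_papers > 0 and not self.drug_names:
            raise ConfigurationError("drug_names must be nonempty when n_papers > 0")


@dataclass
class GroundTruth:
    """What the generators actually planted, for downstream recovery checks."""

    publication_counts: pd.DataFrame | None = None
    record_labels: dict = field(default_factory=dict)
    signal_pairs: frozenset = frozenset()
    ade_pairs: frozenset = frozenset()
    rate_table: pd.DataFrame | None = None
    eligible_persons: frozenset = frozenset()
    exposed_persons: dict = field(default_factory=dict)


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = (np.arange(1, n + 1, dtype=float)) ** (-exponent)
    return w / w.sum()


# ---------------------------------------------------------------------------
# abstract corpus
# ---------------------------------------------------------------------------

def gen_abstract_corpus(config: SimConfig) -> tuple[list[AbstractRecord], GroundTruth]:
    """Generate a literature corpus with known per-drug publication counts.

    Each record embeds every assigned drug name verbatim in exactly one of
    title/abstract/MeSH (uniformly chosen), and one synonym of each assigned
    population tag likewise.  Relevant records carry a study-type combination
    drawn from the reference corpus composition; non-relevant records carry
    no labels.  Per-drug totals follow the configured zipf law.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()
    if config.n_papers == 0:
        truth.publication_counts = pd.DataFrame(
            columns=["drug", "population", "study_type", "paper_count"])
        return [], truth

    drugs = list(config.drug_names)
    dw = _zipf_weights(len(drugs), config.publication_count_law[1])
    combos = list(_STUDY_COMBOS)
    cw = np.array([LABELED_CORPUS_COMPOSITION[c] for c in combos], dtype=float)
    cw /= cw.sum()
    pop_tags = list(POPULATION_TAGS)

    records: list[AbstractRecord] = []
    count_rows: list[tuple] = []
    for i in range(config.n_papers):
        rid = f"PM{i:07d}"
        relevant = bool(rng.random() < config.relevant_fraction)
        labels: frozenset = frozenset()
        if relevant:
            labels = combos[int(rng.choice(len(combos), p=cw))]
        n_drugs = 1 + int(rng.random() < config.multi_drug_prob)
        rec_drugs = list(rng.choice(len(drugs), size=min(n_drugs, len(drugs)),
                                    replace=False, p=dw))
        rec_drugs = [drugs[j] for j in rec_drugs]
        n_pops = 1 + int(rng.random() < 0.3)
        rec_pops = [pop_tags[j] for j in
                    rng.choice(len(pop_tags), size=n_pops, replace=False)]

        title_parts = [f"record {rid} findings"]
        abstract_parts = [_FILLER if relevant else _IRRELEVANT]
        mesh: list[str] = ["Humans"]
        for st in sorted(labels):
            abstract_parts.append(_CUES[st])
        for drug in rec_drugs:
            slot = int(rng.integers(3))  # 0 title, 1 abstract, 2 mesh
            (title_parts, abstract_parts, mesh)[slot].append(drug)
        for tag in rec_pops:
            syns = DEFAULT_POPULATION_SYNONYMS[tag]
            syn = syns[int(rng.integers(len(syns)))]
            slot = int(rng.integers(3))
            (title_parts, abstract_parts, mesh)[slot].append(syn)
        keywords = tuple(sorted(rec_drugs))  # drugs are also scannable keywords
        records.append(AbstractRecord(
            record_id=rid,
            title=" ".join(title_parts),
            abstract=" ".join(abstract_parts),
            mesh_terms=tuple(mesh),
            keywords=keywords,
            year=2016 + int(rng.integers(10)),
        ))
        truth.record_labels[rid] = {
            "relevant": relevant,
            "study_types": labels,
            "drugs": frozenset(rec_drugs),
            "populations": frozenset(rec_pops),
        }
        for drug in rec_drugs:
            for tag in rec_pops:
                for st in sorted(labels):
                    count_rows.append((drug, tag, st))

    counts = (
        pd.DataFrame(count_rows, columns=["drug", "population", "study_type"])
        .groupby(["drug", "population", "study_type"], as_index=False).size()
        .rename(columns={"size": "paper_count"})
        .sort_values(["drug", "population", "study_type"], ignore_index=True)
    )
    truth.publication_counts = counts
    return records, truth


# ---------------------------------------------------------------------------
# spontaneous-report database
# ---------------------------------------------------------------------------

def _draw_reports(rng, n: int, p_drug: np.ndarray, q_event: np.ndarray,
                  boosts: Sequence[tuple[int, int, float]]):
    X = rng.random((n, p_drug.size)) < p_drug
    Y = rng.random((n, q_event.size)) < q_event
    for di, ei, extra in boosts:
        rows = X[:, di] & ~Y[:, ei]
        Y[rows, ei] = rng.random(int(rows.sum())) < extra
    return X, Y


def gen_report_database(config: SimConfig) -> tuple[ReportDatabase, GroundTruth]:
    """Generate spontaneous reports with injected disproportionality signals.

    Each report includes drug d with probability p and event e with
    probability q, independently per item.  For an injected pair (d, e,
    lambda), reports containing d but not e gain e with probability
    (lambda-1)q/(1-q), so that P(e | d) = lambda*q exactly while
    P(e | not d) = q — the pair's relative reporting rate is lambda.  Reports
    with no drug or no event are rejection-resampled, which preserves
    drug-event independence for null pairs.
    """
    truth = GroundTruth(signal_pairs=frozenset(
        (d, e) for d, e, _ in config.injected_signals))
    if config.n_reports == 0:
        return ReportDatabase([]), truth

    rng = np.random.default_rng(config.seed + 1)
    drugs = list(config.drug_names)
    events = list(config.event_names)
    p = np.full(len(drugs), config.report_drug_prob)
    q = np.full(len(events), config.report_event_prob)
    di = {d: i for i, d in enumerate(drugs)}
    ei = {e: i for i, e in enumerate(events)}
    boosts = []
    for d, e, lam in config.injected_signals:
        qe = q[ei[e]]
        extra = (lam - 1.0) * qe / (1.0 - qe)
        if extra > 1.0:
            raise ConfigurationError(
                f"lambda={lam} too large for event marginal {qe} on ({d}, {e})")
        boosts.append((di[d], ei[e], extra))

    X, Y = _draw_reports(rng, config.n_reports, p, q, boosts)
    for _ in range(200):
        bad = ~(X.any(axis=1) & Y.any(axis=1))
        if not bad.any():
            break
        Xb, Yb = _draw_reports(rng, int(bad.sum()), p, q, boosts)
        X[bad], Y[bad] = Xb, Yb
    else:  # pragma: no cover - would need pathological marginals
        raise ConfigurationError("could not sample nonempty reports; raise marginals")

    reports = []
    for r in range(config.n_reports):
        reports.append((
            f"R{r:07d}", "0-2y",
            frozenset(drugs[j] for j in np.flatnonzero(X[r])),
            frozenset(events[j] for j in np.flatnonzero(Y[r])),
        ))
    return ReportDatabase(reports), truth


# ---------------------------------------------------------------------------
# claims cohort
# ---------------------------------------------------------------------------

def gen_claims_cohort(config: SimConfig) -> tuple[ClaimsCohort, GroundTruth]:
    """Generate a claims cohort with pregnancy episodes and injected ADEs.

    Pregnant persons carry exactly one delivery event; eligible persons are
    enrolled over the whole study period while a configurable fraction gets a
    truncated span violating the 270-day lookback.  Pregnancy-window
    prescriptions are anchored so a full exposure window fits before the
    index date.  Baseline diagnoses arrive with a constant per-day hazard
    calibrated so the probability of >= 1 occurrence in any
    ``exposure_window_days`` window equals ``diagnosis_baseline_rate``; for
    an injected (drug, code, exposed, baseline) pair, exposed persons gain an
    extra in-window diagnosis with probability (exposed-baseline)/(1-baseline),
    raising their window probability to exactly ``exposed``.
    """
    rng = np.random.default_rng(config.seed + 2)
    truth = GroundTruth(ade_pairs=frozenset(
        (d, c) for d, c, _, _ in config.injected_ades))
    horizon = config.n_years * 365  # study period [0, horizon)
    W = config.exposure_window_days

    n_preg = int(round(config.pregnancy_fraction * config.n_persons))
    n_ped = config.n_persons - n_preg

    persons_rows, span_rows, rx_rows, dx_rows, delivery_rows = [], [], [], [], []
    rate_tally: dict[tuple[str, str], int] = {}

    # --- pregnant persons -------------------------------------------------
    preg_ids = [f"PG{i:06d}" for i in range(n_preg)]
    index_days = rng.integers(300, max(301, horizon - 190), size=n_preg)
    violates = rng.random(n_preg) < config.enrollment_violation_fraction
    eligible = [pid for pid, v in zip(preg_ids, violates) if not v]
    truth.eligible_persons = frozenset(eligible)

    code_baseline = {c: config.diagnosis_baseline_rate for c in config.icd10_codes}
    for d, c, er, br in config.injected_ades:
        code_baseline[c] = br
    codes = sorted(code_baseline)
    exposed_by_drug: dict[str, set] = {d: set() for d in config.drug_names}
    anchors: dict[tuple[str, str], int] = {}

    drug_list = list(config.drug_names)
    n_drugs = len(drug_list)
    if n_preg:
        # mothers are >= 24 at delivery so they never fall into a pediatric
        # age group during any earlier study year
        births = index_days - rng.integers(24 * 365, 42 * 365, size=n_preg)
        dcodes = rng.integers(len(config.delivery_codes), size=n_preg)
        for i, pid in enumerate(preg_ids):
            idx = int(index_days[i])
            persons_rows.append((pid, int(births[i]), "F"))
            delivery_rows.append((pid, idx, config.delivery_codes[int(dcodes[i])]))
            if violates[i]:
                span_rows.append((pid, idx - 100, min(idx + 200, horizon - 1)))
            else:
                span_rows.append((pid, 0, horizon - 1))
        # pregnancy-window prescriptions: anchors leave room for a full window
        use_preg = rng.random((n_preg, n_drugs)) < config.pregnancy_use_rate
        anchor_mat = index_days[:, None] - rng.integers(
            W, 271, size=(n_preg, n_drugs))
        use_post = rng.random((n_preg, n_drugs)) < config.postpartum_use_rate
        post_days = index_days[:, None] + rng.integers(
            0, 181, size=(n_preg, n_drugs))
        for i, j in zip(*np.nonzero(use_preg)):
            pid, drug = preg_ids[i], drug_list[j]
            a = int(anchor_mat[i, j])
            rx_rows.append((pid, drug, a))
            exposed_by_drug[drug].add(pid)
            anchors[(pid, drug)] = a
            if not violates[i]:
                rate_tally[("pregnancy", drug)] = rate_tally.get(
                    ("pregnancy", drug), 0) + 1
        for i, j in zip(*np.nonzero(use_post)):
            pid, drug = preg_ids[i], drug_list[j]
            rx_rows.append((pid, drug, int(post_days[i, j])))
            if not violates[i]:
                rate_tally[("postpartum", drug)] = rate_tally.get(
                    ("postpartum", drug), 0) + 1

    # baseline diagnoses: constant per-day hazard over [index-270, index]
    if n_preg and codes:
        hazards = np.array([1.0 - (1.0 - code_baseline[c]) ** (1.0 / W)
                            for c in codes])
        counts = rng.binomial(271, hazards, size=(n_preg, len(codes)))
        pi, ci = np.nonzero(counts)
        reps = counts[pi, ci]
        pi = np.repeat(pi, reps)
        ci = np.repeat(ci, reps)
        days = index_days[pi] + rng.integers(-270, 1, size=pi.size)
        for p, c, day in zip(pi, ci, days):
            dx_rows.append((preg_ids[p], codes[c], int(day)))

    # injected ADE boosts inside the exposure window
    for d, c, er, br in config.injected_ades:
        extra = 0.0 if br >= 1.0 else (er - br) / (1.0 - br)
        exposed = sorted(exposed_by_drug[d])
        hits = rng.random(len(exposed)) < extra
        offsets = rng.integers(W, size=len(exposed))
        for pid, hit, off in zip(exposed, hits, offsets):
            if hit:
                dx_rows.append((pid, c, anchors[(pid, d)] + int(off)))

    # --- pediatric persons ------------------------------------------------
    years = [(k * 365, k * 365 + 364) for k in range(config.n_years)]
    ped_ids = [f"PD{i:06d}" for i in range(n_ped)]
    ped_births = rng.integers(-18 * 365, horizon - 1, size=n_ped)
    sexes = rng.integers(2, size=n_ped)
    group_sample = {g[0]: 0 for g in PEDIATRIC_GROUPS}
    for i, pid in enumerate(ped_ids):
        persons_rows.append((pid, int(ped_births[i]), "FM"[int(sexes[i])]))
        span_rows.append((pid, 0, horizon - 1))
    if n_ped:
        use = rng.random((n_ped, len(years), n_drugs)) < config.pediatric_use_rate
        day_off = rng.integers(0, 365, size=(n_ped, len(years), n_drugs))
        for y, (start, end) in enumerate(years):
            mid = (start + end) // 2
            for i in range(n_ped):
                g_mid = age_group_of((mid - int(ped_births[i])) / 365.0)
                if g_mid is not None:
                    group_sample[g_mid] += 1
            for i, j in zip(*np.nonzero(use[:, y, :])):
                birth = int(ped_births[i])
                day = start + int(day_off[i, y, j])
                g = age_group_of((day - birth) / 365.0)
                if g is None:
                    continue
                rx_rows.append((ped_ids[i], drug_list[j], day))
                rate_tally[(g, drug_list[j])] = rate_tally.get(
                    (g, drug_list[j]), 0) + 1

    sample_size = {"pregnancy": len(eligible), "postpartum": len(eligible),
                   **group_sample}
    rate_rows = [
        (sub, drug, n, sample_size[sub], n / sample_size[sub])
        for (sub, drug), n in sorted(rate_tally.items()) if sample_size[sub] > 0
    ]
    truth.rate_table = pd.DataFrame(
        rate_rows, columns=["subpopulation", "drug", "n_prescriptions",
                            "sample_size", "rate"])
    truth.exposed_persons = {d: frozenset(s) for d, s in exposed_by_drug.items()}

    cohort = ClaimsCohort(
        persons=pd.DataFrame(persons_rows,
                             columns=["person_id", "birth_day", "sex"]),
        enrollment_spans=pd.DataFrame(span_rows,
                                      columns=["person_id", "start_day", "end_day"]),
        prescriptions=pd.DataFrame(rx_rows, columns=["person_id", "drug", "day"]),
        diagnoses=pd.DataFrame(dx_rows, columns=["person_id", "icd10_code", "day"]),
        delivery_events=pd.DataFrame(delivery_rows,
                                     columns=["person_id", "day", "code"]),
    )
    return cohort, truth


def study_years(config: SimConfig) -> list[tuple[int, int]]:
    """The (start_day, end_day) year blocks of a generated cohort."""
    return [(k * 365, k * 365 + 364) for k in range(config.n_years)]
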