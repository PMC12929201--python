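"""Readers and writers for the package's delimited-text interchange formats.

Everything is plain text: JSON-lines for abstract corpora and report
databases, MEDLINE-like tagged text (TI/AB/MH/OT fields) for abstracts, CSV
for claims tables, TSV for lexicons, annotations and result tables.  Writers
are deterministic given identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .disproportionality import ReportDatabase, SignalDecision
from .landscape import ClaimsCohort
from .lexicon import AbstractRecord
from .case_control import ScreenResult

__all__ = [
    "corpus_to_jsonl", "corpus_from_jsonl", "corpus_to_medline",
    "reports_to_jsonl", "reports_from_jsonl", "reports_from_delimited",
    "write_cohort", "read_cohort",
    "labeled_corpus_from_jsonl", "labeled_corpus_from_delimited",
    "decisions_to_tsv", "screen_results_to_tsv",
]

_COHORT_TABLES = ("persons", "enrollment_spans", "prescriptions",
                  "diagnoses", "delivery_events")


def corpus_to_jsonl(records: Iterable[AbstractRecord]) -> str:
    lines = []
    for r in records:
        lines.append(json.dumps({
            "record_id": r.record_id, "title": r.title, "abstract": r.abstract,
            "mesh_terms": list(r.mesh_terms), "keywords": list(r.keywords),
            "year": r.year, "language": r.language,
        }, sort_keys=True))
    return "\n".join(lines) + ("\n" if lines else "")


def corpus_from_jsonl(text: str) -> list[AbstractRecord]:
    records = []
    for line in text.splitlines():
        if not line.strip():
            continue
        o = json.loads(line)
        records.append(AbstractRecord(
            record_id=o["record_id"], title=o.get("title", ""),
            abstract=o.get("abstract", ""),
            mesh_terms=tuple(o.get("mesh_terms", ())),
            keywords=tuple(o.get("keywords", ())),
            year=int(o.get("year", 0)), language=o.get("language", "eng")))
    return records


def corpus_to_medline(records: Iterable[AbstractRecord]) -> str:
    """MEDLINE-like tagged text: PMID/TI/AB/MH/OT/DP fields per record."""
    blocks = []
    for r in records:
        lines = [f"PMID- {r.record_id}", f"TI  - {r.title}", f"AB  - {r.abstract}"]
        lines += [f"MH  - {m}" for m in r.mesh_terms]
        lines += [f"OT  - {k}" for k in r.keywords]
        lines.append(f"DP  - {r.year}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def reports_to_jsonl(db: ReportDatabase) -> str:
    lines = []
    for rid, age, drugs, events in db.reports:
        lines.append(json.dumps({
            "report_id": rid, "age_group": age,
            "drugs": sorted(drugs), "events": sorted(events),
        }, sort_keys=True))
    return "\n".join(lines) + ("\n" if lines else "")


def reports_from_jsonl(text: str) -> ReportDatabase:
    reports = []
    for line in text.splitlines():
        if not line.strip():
            continue
        o = json.loads(line)
        reports.append((o["report_id"], o.get("age_group", ""),
                        frozenset(o["drugs"]), frozenset(o["events"])))
    return ReportDatabase(reports)


def reports_from_delimited(text: str, sep: str = "\t") -> ReportDatabase:
    """One row per (report_id, age_group, drug, event) triple, aggregated."""
    acc: dict[str, tuple[str, set, set]] = {}
    for i, line in enumerate(text.splitlines()):
        if not line.strip():
            continue
        parts = line.split(sep)
        if i == 0 and parts[0] in ("report_id", "reportid"):
            continue
        rid, age, drug, event = parts[:4]
        age_, drugs, events = acc.setdefault(rid, (age, set(), set()))
        drugs.add(drug)
        events.add(event)
    return ReportDatabase([
        (rid, age, frozenset(d), frozenset(e))
        for rid, (age, d, e) in sorted(acc.items())
    ])


def write_cohort(cohort: ClaimsCohort, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _COHORT_TABLES:
        path = out_dir / f"{name}.csv"
        getattr(cohort, name).to_csv(path, index=False)
        written.append(path)
    return written


def read_cohort(in_dir: str | Path) -> ClaimsCohort:
    in_dir = Path(in_dir)
    return ClaimsCohort(**{
        name: pd.read_csv(in_dir / f"{name}.csv")
        for name in _COHORT_TABLES
    })


def labeled_corpus_from_jsonl(text: str):
    """JSON-lines dialect: record fields plus 'relevant' and 'labels'."""
    from .triage import LabeledAbstract

    out = []
    for line in text.splitlines():
        if not line.strip():
            continue
        o = json.loads(line)
        rec = AbstractRecord(
            record_id=o["record_id"], title=o.get("title", ""),
            abstract=o.get("abstract", ""),
            mesh_terms=tuple(o.get("mesh_terms", ())),
            keywords=tuple(o.get("keywords", ())),
            year=int(o.get("year", 0)))
        out.append(LabeledAbstract(rec, bool(o["relevant"]),
                                   frozenset(o.get("labels", ()))))
    return out


def labeled_corpus_from_delimited(
    text: str,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
):
    """Delimited labeled-corpus dialect with a configurable column map.

    ``column_map`` maps the logical fields (record_id, title, abstract,
    relevant, labels) to the file's column names; 'labels' holds a
    comma-separated study-type list.
    """
    from io import StringIO

    from .triage import LabeledAbstract

    cmap = {"record_id": "record_id", "title": "title", "abstract": "abstract",
            "relevant": "relevant", "labels": "labels"}
    cmap.update(column_map or {})
    df = pd.read_csv(StringIO(text), sep=sep, dtype=str).fillna("")
    out = []
    for row in df.itertuples(index=False):
        get = lambda field: getattr(row, cmap[field])
        labels = frozenset(x for x in get("labels").split(",") if x)
        rec = AbstractRecord(record_id=get("record_id"), title=get("title"),
                             abstract=get("abstract"))
        relevant = str(get("relevant")).strip().lower() in ("1", "true", "yes", "y")
        out.append(LabeledAbstract(rec, relevant, labels))
    return out


def decisions_to_tsv(decisions: Sequence[SignalDecision]) -> str:
    rows = []
    for d in decisions:
        s = d.stats
        rows.append({
            "drug": d.drug, "event": d.event,
            "prr": s.prr, "prr025": s.prr025, "ror": s.ror, "ror025": s.ror025,
            "ic": s.ic, "ic025": s.ic025, "ebgm": s.ebgm, "eb05": s.eb05,
            "is_signal": d.is_signal, "reason": d.reason or "",
        })
    return pd.DataFrame(rows).to_csv(sep="\t", index=False, float_format="%.6g")


def screen_results_to_tsv(results: Sequence[ScreenResult]) -> str:
    rows = []
    for r in results:
        rows.append({
            "drug": r.drug, "icd10_code": r.icd10_code,
            "exposed_pos": r.table.n11, "exposed_neg": r.table.n10,
            "unexposed_pos": r.table.n01, "unexposed_neg": r.table.n00,
            "chi2": r.chi2, "p_value": r.p_value,
            "passes_threshold": r.passes_threshold,
            "filtered_reason": r.filtered_reason or "",
            "is_new_ade": r.is_new_ade,
        })
    return pd.DataFrame(rows).to_csv(sep="\t", index=False, float_format="%.6g")
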