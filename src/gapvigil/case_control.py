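"""Nested case-control screen for drug-associated diagnoses in pregnancy.

For one drug, pregnant persons with a qualifying prescription are the
exposed group: their observation window of ``window_days`` (default 60,
"two months") starts at the first prescription whose window fits inside the
pregnancy period [index-270, index]; windows that would overrun the index
day are clamped at it.  Unexposed persons receive a comparison window of
equal length whose start offset (relative to the index date) is sampled,
with a seed, from the empirical distribution of the exposed offsets — the
design's way of giving controls an observation window comparable to cases'.

A person is outcome-positive for an ICD-10 code if at least one diagnosis of
that code falls inside their window (person-level indicator; repeats count
once).  Each code's exposed x outcome 2x2 table is tested with a Pearson
chi-square (1 df, no continuity correction by default) against a stringent
fixed p-value threshold (default 1e-5) standing in for multiplicity control.
Codes matching configured blocklists (pregnancy-related, indication-related,
label-known, literature-known prefixes) are excluded from the new-ADE report
with their first-matching reason, but retained in the full output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .disproportionality import ContingencyTable
from .landscape import PREGNANCY_LOOKBACK_DAYS, PregnancyEpisode

__all__ = [
    "ExposureAssignment",
    "ScreenResult",
    "ScreenConfig",
    "assign_exposure",
    "collect_outcomes",
    "chi_square_screen",
    "filter_codes",
    "run_screen",
]

DEFAULT_WINDOW_DAYS = 60
DEFAULT_P_THRESHOLD = 1e-5

#: blocklist precedence: first match wins
FILTER_REASONS = ("pregnancy_related", "indication_related",
                  "label_known", "literature_known")


@dataclass(frozen=True)
class ExposureAssignment:
    person_id: object
    exposed: bool
    window_start: int
    window_end: int
    anchor: int  # first qualifying prescription day, or sampled control start


@dataclass(frozen=True)
class ScreenResult:
    drug: str
    icd10_code: str
    table: ContingencyTable
    chi2: float
    p_value: float
    passes_threshold: bool
    filtered_reason: str | None = None

    @property
    def is_new_ade(self) -> bool:
        return self.passes_threshold and self.filtered_reason is None


def assign_exposure(
    episodes: Sequence[PregnancyEpisode],
    prescriptions: pd.DataFrame,
    drug: str,
    window_days: int = DEFAULT_WINDOW_DAYS,
    seed: int = 0,
) -> list[ExposureAssignment]:
    """Split eligible episodes into exposed/unexposed with observation windows.

    Exposed: first prescription of ``drug`` in [index-270, index]; the window
    starts there and is clamped so it never passes the index day.  Unexposed
    persons get a window whose start offset is drawn (seeded) from the
    empirical exposed-offset distribution.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    eligible = [e for e in episodes if e.eligible]
    index_of = {e.person_id: e.index_day for e in eligible}
    rx = prescriptions[(prescriptions["drug"] == drug)
                       & prescriptions["person_id"].isin(index_of)]
    first_rx: dict = {}
    for pid, day in zip(rx["person_id"], rx["day"]):
        idx = index_of[pid]
        if idx - PREGNANCY_LOOKBACK_DAYS <= day <= idx:
            if pid not in first_rx or day < first_rx[pid]:
                first_rx[pid] = int(day)
    if not first_rx:
        raise ValueError(f"no exposed persons for drug {drug!r}; screen not estimable")

    exposed_offsets = np.array(sorted(first_rx[p] - index_of[p] for p in first_rx))
    rng = np.random.default_rng(seed)
    out = []
    for e in sorted(eligible, key=lambda e: str(e.person_id)):
        idx = e.index_day
        if e.person_id in first_rx:
            start = first_rx[e.person_id]
            out.append(ExposureAssignment(
                e.person_id, True, start,
                min(start + window_days - 1, idx), start))
        else:
            off = int(exposed_offsets[rng.integers(len(exposed_offsets))])
            start = idx + off
            out.append(ExposureAssignment(
                e.person_id, False, start,
                min(start + window_days - 1, idx), start))
    return out


def collect_outcomes(
    assignments: Sequence[ExposureAssignment],
    diagnoses: pd.DataFrame,
    codes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Person-level outcome indicators per ICD-10 code within each window.

    Returns one row per (icd10_code): counts of exposed/unexposed persons
    with and without >= 1 in-window diagnosis of the code.
    """
    if not assignments:
        raise ValueError("no exposure assignments")
    win = pd.DataFrame(
        [(a.person_id, a.exposed, a.window_start, a.window_end)
         for a in assignments],
        columns=["person_id", "exposed", "window_start", "window_end"],
    )
    n_exposed = int(win["exposed"].sum())
    n_unexposed = len(win) - n_exposed
    dx = diagnoses.merge(win, on="person_id")
    dx = dx[(dx["day"] >= dx["window_start"]) & (dx["day"] <= dx["window_end"])]
    if codes is not None:
        dx = dx[dx["icd10_code"].isin(set(codes))]
    hit = dx.drop_duplicates(["person_id", "icd10_code"])
    grouped = hit.groupby(["icd10_code", "exposed"]).size().unstack(fill_value=0)
    all_codes = sorted(set(codes)) if codes is not None else sorted(grouped.index)
    rows = []
    for code in all_codes:
        pos_exp = int(grouped.at[code, True]) if (
            code in grouped.index and True in grouped.columns) else 0
        pos_une = int(grouped.at[code, False]) if (
            code in grouped.index and False in grouped.columns) else 0
        rows.append((code, pos_exp, n_exposed - pos_exp,
                     pos_une, n_unexposed - pos_une))
    return pd.DataFrame(rows, columns=[
        "icd10_code", "exposed_pos", "exposed_neg",
        "unexposed_pos", "unexposed_neg"])


def chi_square_screen(
    table: ContingencyTable, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) on the exposed x outcome 2x2 table.

    Cells: n11 = exposed with outcome, n10 = exposed without, n01 = unexposed
    with, n00 = unexposed without.  Zero margins leave the statistic
    undefined (nan).
    """
    a, b, c, d = table.n11, table.n10, table.n01, table.n00
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m <= 0 for m in margins):
        return float("nan"), float("nan")
    if continuity_correction:
        num = n * max(0.0, abs(a * d - b * c) - n / 2.0) ** 2
    else:
        num = n * (a * d - b * c) ** 2
    chi2 = num / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def filter_codes(
    results: Sequence[ScreenResult],
    blocklists: Mapping[str, Sequence[str]],
) -> list[ScreenResult]:
    """Tag results whose code matches any blocklist prefix.

    ``blocklists`` maps reason -> list of code prefixes; reasons are applied
    in the fixed precedence ``FILTER_REASONS`` and the first match wins.
    All results are returned, with ``filtered_reason`` set where applicable.
    """
    unknown = set(blocklists) - set(FILTER_REASONS)
    if unknown:
        raise ValueError(f"unknown blocklist reasons: {sorted(unknown)}")
    out = []
    for r in results:
        reason = None
        for name in FILTER_REASONS:
            prefixes = blocklists.get(name, ())
            if any(r.icd10_code.startswith(p) for p in prefixes):
                reason = name
                break
        out.append(ScreenResult(r.drug, r.icd10_code, r.table, r.chi2,
                                r.p_value, r.passes_threshold, reason))
    return out


@dataclass(frozen=True)
class ScreenConfig:
    window_days: int = DEFAULT_WINDOW_DAYS
    p_threshold: float = DEFAULT_P_THRESHOLD
    continuity_correction: bool = False
    seed: int = 0


def run_screen(
    episodes: Sequence[PregnancyEpisode],
    drugs: Sequence[str],
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
    codes: Iterable[str] | None = None,
    blocklists: Mapping[str, Sequence[str]] | None = None,
) -> list[ScreenResult]:
    """Full screen: exposure, outcomes, chi-square, threshold, code filters."""
    results: list[ScreenResult] = []
    for drug in drugs:
        try:
            assignments = assign_exposure(episodes, prescriptions, drug,
                                          config.window_days, config.seed)
        except ValueError as exc:
            raise ValueError(f"drug {drug!r}: {exc}") from exc
        outcomes = collect_outcomes(assignments, diagnoses, codes)
        for row in outcomes.itertuples(index=False):
            t = ContingencyTable(row.exposed_pos, row.exposed_neg,
                                 row.unexposed_pos, row.unexposed_neg)
            chi2, p = chi_square_screen(t, config.continuity_correction)
            passes = bool(p < config.p_threshold) if np.isfinite(p) else False
            results.append(ScreenResult(drug, row.icd10_code, t, chi2, p, passes))
    if blocklists:
        results = filter_codes(results, blocklists)
    return results
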