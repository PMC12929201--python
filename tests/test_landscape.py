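"""Pregnancy/postpartum windowing, pediatric rates, evidence gaps, ranking."""

import numpy as np
import pandas as pd
import pytest

from gapvigil.landscape import (
    ADEQUATE,
    NO_EVIDENCE,
    WEAK_EVIDENCE,
    build_pregnancy_cohort,
    classify_evidence,
    filter_min_prescriptions,
    format_miss_probability,
    gap_summary,
    miss_probability,
    pediatric_rates,
    pregnancy_postpartum_rates,
    rank_no_evidence,
    window_prescription_counts,
)
from gapvigil.landscape import ClaimsCohort, PregnancyEpisode


def _episode(person="p", index=1000, eligible=True):
    return PregnancyEpisode(person, index, eligible)


def _rx(rows):
    return pd.DataFrame(rows, columns=["person_id", "drug", "day"])


class TestBuildPregnancyCohort:
    def test_superset_span_is_eligible(self, tiny_cohort):
        episodes = build_pregnancy_cohort(tiny_cohort, ["O80"])
        by_person = {e.person_id: e for e in episodes}
        assert by_person["a"].eligible

    def test_short_lookback_is_ineligible(self, tiny_cohort):
        episodes = build_pregnancy_cohort(tiny_cohort, ["O80"])
        by_person = {e.person_id: e for e in episodes}
        assert not by_person["b"].eligible

    def test_index_is_first_delivery_day(self):
        persons = pd.DataFrame({"person_id": ["a"], "birth_day": [-9000],
                                "sex": ["F"]})
        spans = pd.DataFrame({"person_id": ["a"], "start_day": [0],
                              "end_day": [3000]})
        empty_rx = _rx([])
        dx = pd.DataFrame(columns=["person_id", "icd10_code", "day"])
        deliveries = pd.DataFrame({"person_id": ["a", "a"], "day": [1500, 1200],
                                   "code": ["O80", "O80"]})
        cohort = ClaimsCohort(persons, spans, empty_rx, dx, deliveries)
        (episode,) = build_pregnancy_cohort(cohort, ["O80"])
        assert episode.index_day == 1200

    def test_gap_between_spans_breaks_continuity(self):
        persons = pd.DataFrame({"person_id": ["a"], "birth_day": [-9000],
                                "sex": ["F"]})
        spans = pd.DataFrame({"person_id": ["a", "a"],
                              "start_day": [600, 1001],
                              "end_day": [999, 1300]})
        dx = pd.DataFrame(columns=["person_id", "icd10_code", "day"])
        deliveries = pd.DataFrame({"person_id": ["a"], "day": [1000],
                                   "code": ["O80"]})
        cohort = ClaimsCohort(persons, spans, _rx([]), dx, deliveries)
        (episode,) = build_pregnancy_cohort(cohort, ["O80"])
        assert not episode.eligible  # day 1000 uncovered

    def test_adjacent_spans_merge(self):
        persons = pd.DataFrame({"person_id": ["a"], "birth_day": [-9000],
                                "sex": ["F"]})
        spans = pd.DataFrame({"person_id": ["a", "a"],
                              "start_day": [600, 1000],
                              "end_day": [999, 1300]})
        dx = pd.DataFrame(columns=["person_id", "icd10_code", "day"])
        deliveries = pd.DataFrame({"person_id": ["a"], "day": [1000],
                                   "code": ["O80"]})
        cohort = ClaimsCohort(persons, spans, _rx([]), dx, deliveries)
        (episode,) = build_pregnancy_cohort(cohort, ["O80"])
        assert episode.eligible

    def test_empty_delivery_codes_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            build_pregnancy_cohort(tiny_cohort, [])


class TestWindowing:
    @pytest.mark.parametrize("day,expected", [
        (999, "pregnancy"),     # index-1
        (1000, "postpartum"),   # index day
        (730, "pregnancy"),     # index-270
        (729, None),            # index-271: outside both windows
        (1180, "postpartum"),   # index+180
        (1181, None),
    ])
    def test_boundaries(self, day, expected):
        counts = window_prescription_counts(
            [_episode()], _rx([("p", "drugx", day)]))
        if expected is None:
            assert len(counts) == 0
        else:
            assert counts["subpopulation"].tolist() == [expected]

    def test_windows_partition_range(self):
        # every day in [index-270, index+180] lands in exactly one window
        days = np.arange(1000 - 270, 1000 + 181)
        counts = window_prescription_counts(
            [_episode()], _rx([("p", "drugx", int(d)) for d in days]))
        assert counts["n_prescriptions"].sum() == len(days)

    def test_ineligible_episodes_excluded(self):
        counts = window_prescription_counts(
            [_episode(eligible=False)], _rx([("p", "drugx", 999)]))
        assert len(counts) == 0

    def test_event_vs_person_level_counting(self):
        rx = _rx([("p", "drugx", 900), ("p", "drugx", 910)])
        event = window_prescription_counts([_episode()], rx)
        person = window_prescription_counts([_episode()], rx,
                                            distinct_persons=True)
        assert event["n_prescriptions"].tolist() == [2]
        assert person["n_prescriptions"].tolist() == [1]

    def test_rates_use_eligible_sample_size(self):
        episodes = [_episode("p"), _episode("q", eligible=False)]
        rates = pregnancy_postpartum_rates(episodes, _rx([("p", "drugx", 999)]))
        assert rates["sample_size"].tolist() == [1]
        assert rates["rate_per_1000"].tolist() == [1000.0]


class TestPediatricRates:
    def _cohort(self, persons, rx):
        p = pd.DataFrame(persons, columns=["person_id", "birth_day", "sex"])
        spans = pd.DataFrame({"person_id": p["person_id"],
                              "start_day": 0, "end_day": 4000})
        dx = pd.DataFrame(columns=["person_id", "icd10_code", "day"])
        dv = pd.DataFrame(columns=["person_id", "day", "code"])
        return ClaimsCohort(p, spans, _rx(rx), dx, dv)

    def test_person_crossing_group_boundary_counts_in_each(self):
        # age ~0.5 during year one, ~1.5 during year two
        cohort = self._cohort([("k", -180, "F")],
                              [("k", "drugx", 10), ("k", "drugx", 400)])
        table, _ = pediatric_rates(cohort, [(0, 364), (365, 729)])
        got = dict(zip(table["subpopulation"], table["n_prescriptions"]))
        assert got == {"ped_0_1": 1, "ped_1_12": 1}

    def test_age_exactly_one_goes_to_older_group(self):
        cohort = self._cohort([("k", 0, "F")], [("k", "drugx", 365)])
        table, _ = pediatric_rates(cohort, [(365, 729)])
        assert table["subpopulation"].tolist() == ["ped_1_12"]

    def test_age_nineteen_excluded(self):
        cohort = self._cohort([("k", -19 * 365, "F")], [("k", "drugx", 10)])
        table, _ = pediatric_rates(cohort, [(0, 364)])
        assert len(table) == 0

    def test_negative_age_skipped_with_count(self):
        cohort = self._cohort([("k", 500, "F")], [("k", "drugx", 10)])
        table, n_neg = pediatric_rates(cohort, [(0, 364)])
        assert n_neg == 1 and len(table) == 0

    def test_sample_sizes_cumulative_across_years(self):
        cohort = self._cohort([("k", -1000, "F")], [("k", "drugx", 100)])
        table, _ = pediatric_rates(cohort, [(0, 364), (365, 729)])
        # the child is 2-4 in both years: sample size 2 in ped_1_12
        assert table["sample_size"].tolist() == [2]


class TestFilterAndEvidence:
    def test_threshold_is_strict(self):
        table = pd.DataFrame({"subpopulation": ["s"] * 2, "drug": ["a", "b"],
                              "n_prescriptions": [10, 11]})
        kept = filter_min_prescriptions(table, 10)
        assert kept["drug"].tolist() == ["b"]

    def test_empty_table_passthrough(self):
        table = pd.DataFrame(columns=["n_prescriptions"])
        assert len(filter_min_prescriptions(table)) == 0

    def test_zero_threshold_keeps_any_positive(self):
        table = pd.DataFrame({"n_prescriptions": [1, 0]})
        assert filter_min_prescriptions(table, 0)["n_prescriptions"].tolist() == [1]

    @pytest.mark.parametrize("count,expected", [
        (0, NO_EVIDENCE), (1, WEAK_EVIDENCE), (4, WEAK_EVIDENCE),
        (5, ADEQUATE), (500, ADEQUATE),
    ])
    def test_evidence_classes(self, count, expected):
        assert classify_evidence(count) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            classify_evidence(-1)


def _rate_table(drugs, subpop="pregnancy", n=100):
    return pd.DataFrame({
        "subpopulation": [subpop] * len(drugs),
        "drug": drugs,
        "n_prescriptions": [n] * len(drugs),
        "sample_size": [1000] * len(drugs),
        "rate": [n / 1000] * len(drugs),
    })


def _pub_table(counts, subpop_tag="pregnancy", study_type="PK"):
    return pd.DataFrame({
        "drug": list(counts),
        "population": [subpop_tag] * len(counts),
        "study_type": [study_type] * len(counts),
        "paper_count": list(counts.values()),
    })


class TestGapSummary:
    def test_enumeration_example(self):
        # 10 drugs: 3 no-evidence, 2 weak (3 papers), 5 adequate -> 0.5
        drugs = [f"d{i}" for i in range(10)]
        pubs = _pub_table({**{d: 9 for d in drugs[:5]},
                           **{d: 3 for d in drugs[5:7]}})
        summary = gap_summary(_rate_table(drugs), pubs)
        cell = summary.cell("pregnancy", "PK")
        assert cell["n_no_evidence"] == 3 and cell["n_weak"] == 2
        assert cell["relative_frequency"] == 0.5

    def test_all_adequate_gives_zero(self):
        drugs = ["a", "b"]
        summary = gap_summary(_rate_table(drugs), _pub_table({"a": 7, "b": 5}))
        assert summary.cell("pregnancy", "PK")["relative_frequency"] == 0.0

    def test_components_sum_to_total(self):
        drugs = [f"d{i}" for i in range(7)]
        pubs = _pub_table({drugs[0]: 2, drugs[1]: 6})
        summary = gap_summary(_rate_table(drugs), pubs)
        for _, row in summary.cells.iterrows():
            assert (row["n_no_evidence"] + row["n_weak"] + row["n_adequate"]
                    == row["n_drugs_total"])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            gap_summary(pd.DataFrame(columns=["subpopulation", "drug",
                                              "n_prescriptions"]),
                        _pub_table({"a": 1}))


class TestRankNoEvidence:
    def test_sorted_by_prescriptions_desc(self):
        rates = _rate_table(["hi", "lo"])
        rates.loc[rates["drug"] == "hi", "n_prescriptions"] = 100
        rates.loc[rates["drug"] == "lo", "n_prescriptions"] = 50
        ranked = rank_no_evidence(rates, _pub_table({}), "pregnancy")
        assert ranked == ["hi", "lo"]

    def test_no_zero_evidence_drugs_gives_empty(self):
        ranked = rank_no_evidence(_rate_table(["a"]), _pub_table({"a": 1}),
                                  "pregnancy")
        assert ranked == []

    def test_any_study_type_evidence_disqualifies(self):
        pubs = _pub_table({"a": 2}, study_type="CT")
        ranked = rank_no_evidence(_rate_table(["a", "b"]), pubs, "pregnancy")
        assert ranked == ["b"]

    def test_tie_breaks_alphabetically(self):
        ranked = rank_no_evidence(_rate_table(["zed", "abc"]), _pub_table({}),
                                  "pregnancy")
        assert ranked == ["abc", "zed"]


class TestMissProbability:
    def test_reported_bound_for_weak_evidence(self):
        assert miss_probability(0.93, 4) == pytest.approx(0.0024, abs=5e-5)
        assert format_miss_probability(0.93, 4) == "0.0024%"

    def test_perfect_recall(self):
        assert miss_probability(1.0, 7) == 0.0
        assert format_miss_probability(1.0, 7) == "0%"

    def test_zero_recall(self):
        assert miss_probability(0.0, 3) == 100.0

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            miss_probability(1.2, 1)
        with pytest.raises(ValueError):
            miss_probability(0.5, -1)
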