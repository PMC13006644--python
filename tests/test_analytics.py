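"""Cohorts, characterisation, incidence (vs brute-force oracle), pathways."""

import datetime as dt

import pytest

from surveyomop.analytics import (
    CohortDefinition,
    TimeAtRiskWindow,
    build_cohort,
    characterize_cohort,
    incidence_rates,
    pathway_sequences,
)
from surveyomop.etl import CdmBundle, _table

D = dt.date


def make_cdm(conditions, persons=None):
    """conditions: (person_id, concept_id, date) triples."""
    person_ids = sorted({p for p, _, _ in conditions} | set(persons or []))
    person_rows = [
        {
            "person_id": pid,
            "gender_concept_id": 8532 if pid % 2 else 8507,
            "year_of_birth": 1980,
            "month_of_birth": 6,
            "day_of_birth": 15,
            "race_concept_id": 0,
            "ethnicity_concept_id": 0,
            "location_id": None,
            "person_source_value": f"p{pid}",
            "gender_source_value": None,
            "race_source_value": None,
            "ethnicity_source_value": None,
        }
        for pid in person_ids
    ]
    cond_rows = [
        {
            "condition_occurrence_id": k + 1,
            "person_id": pid,
            "condition_concept_id": cid,
            "condition_start_date": date,
            "condition_type_concept_id": 32862,
            "visit_occurrence_id": None,
            "condition_source_value": "",
        }
        for k, (pid, cid, date) in enumerate(conditions)
    ]
    return CdmBundle(
        person=_table("person", person_rows),
        condition_occurrence=_table("condition_occurrence", cond_rows),
    )


ANX = 2_000_000_101
DEP = 2_000_000_102


def cohort(cid, concept, restriction="earliest_event_only"):
    return CohortDefinition(cid, "condition_occurrence", (concept,), restriction=restriction)


class TestBuildCohort:
    def test_earliest_event_keeps_one_membership_at_earliest_date(self):
        cdm = make_cdm([(1, ANX, D(2020, 5, 1)), (1, ANX, D(2019, 2, 1)), (1, ANX, D(2021, 1, 1))])
        members = build_cohort(cdm, cohort("anx", ANX))
        assert len(members) == 1
        assert members[0].index_date == D(2019, 2, 1)

    def test_no_qualifying_events_gives_empty_cohort(self):
        cdm = make_cdm([(1, ANX, D(2020, 5, 1))])
        assert build_cohort(cdm, cohort("dep", DEP)) == []

    def test_same_date_tie_yields_single_membership(self):
        cdm = make_cdm([(1, ANX, D(2020, 5, 1)), (1, ANX, D(2020, 5, 1))])
        members = build_cohort(cdm, cohort("anx", ANX))
        assert len(members) == 1 and members[0].index_date == D(2020, 5, 1)

    def test_empty_concept_set_is_fatal(self):
        with pytest.raises(ValueError, match="non-empty"):
            CohortDefinition("x", "condition_occurrence", ())

    def test_earliest_event_law_distinct_persons_equal_memberships(self):
        events = [
            (pid, ANX, D(2019 + (pid * k) % 4, 1 + (pid + k) % 12, 1 + (k * 7) % 28))
            for pid in range(1, 30)
            for k in range(3)
        ]
        members = build_cohort(make_cdm(events), cohort("anx", ANX))
        assert len(members) == len({m.person_id for m in members})


class TestCharacterize:
    def test_gender_counts_and_proportions(self):
        cdm = make_cdm([(pid, ANX, D(2020, 1, 1)) for pid in range(1, 11)])
        members = build_cohort(cdm, cohort("anx", ANX))
        table = characterize_cohort(cdm, members, features=("gender",))
        female = table[table.category == "8532"].iloc[0]
        assert female["count"] == 5 and female.proportion == 0.5

    def test_proportions_sum_to_one_per_feature(self):
        cdm = make_cdm([(pid, ANX, D(2018 + pid % 3, 1, 1)) for pid in range(1, 14)])
        members = build_cohort(cdm, cohort("anx", ANX))
        table = characterize_cohort(cdm, members)
        for feature, grp in table.groupby("feature"):
            if grp.proportion.notna().all():
                assert grp.proportion.sum() == pytest.approx(1.0)

    def test_age_bands_partition_members(self):
        cdm = make_cdm([(pid, ANX, D(2020, 1, 1)) for pid in range(1, 9)])
        members = build_cohort(cdm, cohort("anx", ANX))
        table = characterize_cohort(cdm, members, features=("age_group",))
        assert table["count"].sum() == len(members)

    def test_empty_cohort_gives_empty_table(self):
        cdm = make_cdm([(1, ANX, D(2020, 1, 1))])
        assert characterize_cohort(cdm, []).empty


class TestIncidence:
    def test_rate_arithmetic(self):
        # engineered: 10 target members, 2 cases, rate = 1000*cases/PY
        targets = [(pid, ANX, D(2020, 1, 1)) for pid in range(1, 11)]
        outcomes = [(1, DEP, D(2020, 3, 1)), (2, DEP, D(2020, 6, 1)), (3, DEP, D(2025, 1, 1))]
        cdm = make_cdm(targets + outcomes)
        (row,) = incidence_rates(
            cdm, [cohort("anx", ANX)], cohort("dep", DEP), TimeAtRiskWindow(0, 365)
        )
        assert row.persons_at_risk == 10
        assert row.cases == 2  # the 2025 outcome is outside the window
        assert row.cases_per_1000_persons == pytest.approx(200.0)
        assert row.rate_per_1000_py == pytest.approx(1000 * row.cases / row.person_years)

    def test_zero_cases_yields_zero_rates(self):
        cdm = make_cdm([(pid, ANX, D(2020, 1, 1)) for pid in range(1, 6)])
        (row,) = incidence_rates(cdm, [cohort("anx", ANX)], cohort("dep", DEP))
        assert row.cases == 0
        assert row.rate_per_1000_py == 0.0

    def test_outcome_before_window_start_is_not_a_case(self):
        cdm = make_cdm([(1, ANX, D(2020, 1, 1)), (1, DEP, D(2020, 1, 5))])
        (row,) = incidence_rates(
            cdm, [cohort("anx", ANX)], cohort("dep", DEP), TimeAtRiskWindow(30, 365)
        )
        assert row.cases == 0

    def test_agreement_with_brute_force_day_count_oracle(self):
        import numpy as np

        rng = np.random.default_rng(17)
        events = []
        for pid in range(1, 120):
            for _ in range(int(rng.integers(0, 3))):
                events.append(
                    (pid, ANX, D(2019, 1, 1) + dt.timedelta(days=int(rng.integers(0, 1200))))
                )
            for _ in range(int(rng.integers(0, 3))):
                events.append(
                    (pid, DEP, D(2019, 1, 1) + dt.timedelta(days=int(rng.integers(0, 1200))))
                )
        cdm = make_cdm(events, persons=range(1, 120))
        window = TimeAtRiskWindow(14, 500)
        (row,) = incidence_rates(cdm, [cohort("anx", ANX)], cohort("dep", DEP), window)

        # oracle: walk every member's window day by day
        anx_first: dict[int, dt.date] = {}
        dep_first: dict[int, dt.date] = {}
        for pid, cid, date in events:
            book = anx_first if cid == ANX else dep_first
            if pid not in book or date < book[pid]:
                book[pid] = date
        persons = cases = days = 0
        for pid, index in anx_first.items():
            start = index + dt.timedelta(days=window.start_offset_days)
            end = index + dt.timedelta(days=window.end_offset_days)
            if end < start:
                continue
            persons += 1
            outcome = dep_first.get(pid)
            day = start
            while day <= end:
                days += 1
                if outcome is not None and day == outcome:
                    cases += 1
                    break
                day += dt.timedelta(days=1)
        assert row.persons_at_risk == persons
        assert row.cases == cases
        assert row.person_years == pytest.approx(days / 365.25, abs=1e-9)
        if days:
            assert row.rate_per_1000_py == pytest.approx(1000 * cases / (days / 365.25), abs=1e-9)

    def test_rate_consistency_identity(self):
        cdm = make_cdm(
            [(pid, ANX, D(2020, 1, 1)) for pid in range(1, 8)]
            + [(2, DEP, D(2020, 4, 1)), (5, DEP, D(2020, 2, 2))]
        )
        (row,) = incidence_rates(cdm, [cohort("anx", ANX)], cohort("dep", DEP))
        assert row.rate_per_1000_py * row.person_years / 1000 == pytest.approx(
            row.cases, abs=1e-9
        )


class TestPathways:
    def test_ordered_sequence(self):
        cdm = make_cdm([(1, ANX, D(2020, 1, 1)), (1, DEP, D(2021, 1, 1))])
        assert pathway_sequences(cdm, [cohort("A", ANX), cohort("B", DEP)]) == {"A→B": 1}

    def test_single_cohort_entry(self):
        cdm = make_cdm([(1, DEP, D(2021, 1, 1))])
        assert pathway_sequences(cdm, [cohort("A", ANX), cohort("B", DEP)]) == {"B": 1}

    def test_same_date_entries_collapse_to_set(self):
        cdm = make_cdm([(1, ANX, D(2020, 1, 1)), (1, DEP, D(2020, 1, 1))])
        assert pathway_sequences(cdm, [cohort("A", ANX), cohort("B", DEP)]) == {"{A,B}": 1}

    def test_counts_conserve_persons(self):
        cdm = make_cdm(
            [(1, ANX, D(2020, 1, 1)), (2, DEP, D(2020, 1, 1)),
             (3, ANX, D(2020, 1, 1)), (3, DEP, D(2019, 1, 1))]
        )
        sequences = pathway_sequences(cdm, [cohort("A", ANX), cohort("B", DEP)])
        assert sum(sequences.values()) == 3
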