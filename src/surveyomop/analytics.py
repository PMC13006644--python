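"""Cohort construction and descriptive analytics over a CDM bundle.

Cohorts are defined declaratively: an entry criterion (domain table, concept
set, optional value predicate) plus a restriction.  Under the default
``earliest_event_only`` restriction each person contributes exactly one
membership, indexed at their earliest qualifying event — making persons and
episodes one-to-one and avoiding repeated-measures bias in descriptive
comparisons.  Ties at the earliest date are broken by the smallest record
identifier; simultaneous first entries in pathway analysis are collapsed
into an unordered set rather than arbitrarily ordered.

Incidence rates follow the person-time convention: cumulative days at risk
(censored at the outcome) divided by 365.25, cases per 1,000 persons and
per 1,000 person-years.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .etl import CdmBundle

__all__ = [
    "CohortDefinition",
    "CohortMembership",
    "TimeAtRiskWindow",
    "IncidenceRow",
    "build_cohort",
    "characterize_cohort",
    "incidence_rates",
    "pathway_sequences",
]

_DOMAIN_FIELDS = {
    "measurement": ("measurement_concept_id", "measurement_date", "measurement_id"),
    "observation": ("observation_concept_id", "observation_date", "observation_id"),
    "condition_occurrence": (
        "condition_concept_id",
        "condition_start_date",
        "condition_occurrence_id",
    ),
}


@dataclass(frozen=True)
class CohortDefinition:
    cohort_id: str
    domain: str  # measurement | observation | condition_occurrence
    concept_ids: tuple[int, ...]
    min_value: Optional[float] = None
    max_value: Optional[float] = None
    restriction: str = "earliest_event_only"  # or "all_events"

    def __post_init__(self) -> None:
        if self.domain not in _DOMAIN_FIELDS:
            raise ValueError(f"unknown cohort domain {self.domain!r}")
        if not self.concept_ids:
            raise ValueError("cohort concept set must be non-empty")
        if self.restriction not in ("earliest_event_only", "all_events"):
            raise ValueError(f"unknown restriction {self.restriction!r}")


@dataclass(frozen=True)
class CohortMembership:
    cohort_id: str
    person_id: int
    index_date: dt.date


def _qualifying_events(cdm: CdmBundle, defn: CohortDefinition) -> list[tuple[int, dt.date, int]]:
    """(person_id, event_date, record_id) rows matching the entry criterion."""
    concept_field, date_field, id_field = _DOMAIN_FIELDS[defn.domain]
    df = cdm.tables()[defn.domain]
    ids = set(defn.concept_ids)
    events = []
    for row in df.itertuples(index=False):
        if getattr(row, concept_field) not in ids:
            continue
        date = getattr(row, date_field)
        if date is None:
            continue
        if defn.min_value is not None or defn.max_value is not None:
            value = getattr(row, "value_as_number", None)
            if value is None:
                continue
            if defn.min_value is not None and value < defn.min_value:
                continue
            if defn.max_value is not None and value > defn.max_value:
                continue
        events.append((row.person_id, date, getattr(row, id_field)))
    return events


def build_cohort(cdm: CdmBundle, defn: CohortDefinition) -> list[CohortMembership]:
    """Materialise cohort memberships.

    Under ``earliest_event_only`` at most one membership per person, at the
    earliest qualifying event date (ties: smallest record id, which only
    affects which *event* qualifies, not the index date).
    """
    events = _qualifying_events(cdm, defn)
    if defn.restriction == "all_events":
        return [
            CohortMembership(defn.cohort_id, pid, date)
            for pid, date, _rid in sorted(events, key=lambda e: (e[0], e[1], e[2]))
        ]
    best: dict[int, tuple[dt.date, int]] = {}
    for pid, date, rid in events:
        cur = best.get(pid)
        if cur is None or (date, rid) < cur:
            best[pid] = (date, rid)
    return [
        CohortMembership(defn.cohort_id, pid, date)
        for pid, (date, _rid) in sorted(best.items())
    ]


def _birth_date(row) -> Optional[dt.date]:
    if row.year_of_birth is None:
        return None
    # missing month/day default to July 1 (mid-year convention)
    return dt.date(
        int(row.year_of_birth),
        int(row.month_of_birth) if row.month_of_birth is not None else 7,
        int(row.day_of_birth) if row.day_of_birth is not None else 1,
    )


DEFAULT_FEATURES = ("index_year", "gender", "age_at_index", "age_group", "race", "ethnicity")


def characterize_cohort(
    cdm: CdmBundle,
    memberships: Sequence[CohortMembership],
    features: Sequence[str] = DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Univariate descriptive statistics per feature.

    Categorical features yield (feature, category, count, proportion) rows
    whose proportions sum to 1 within the feature; ``age_at_index`` yields a
    single mean row.  Age groups are 10-year bands.
    """
    person = {row.person_id: row for row in cdm.person.itertuples(index=False)}
    rows: list[dict] = []
    n = len(memberships)
    if n == 0:
        return pd.DataFrame(columns=["feature", "category", "count", "proportion", "mean"])

    def ages():
        for m in memberships:
            birth = _birth_date(person[m.person_id])
            if birth is not None:
                yield (m.index_date - birth).days / 365.25

    def categorical(feature: str, values) -> None:
        counts: dict[str, int] = {}
        for v in values:
            counts[str(v)] = counts.get(str(v), 0) + 1
        total = sum(counts.values())
        for cat in sorted(counts):
            rows.append(
                {
                    "feature": feature,
                    "category": cat,
                    "count": counts[cat],
                    "proportion": counts[cat] / total,
                    "mean": None,
                }
            )

    for feature in features:
        if feature == "index_year":
            categorical(feature, (m.index_date.year for m in memberships))
        elif feature == "gender":
            categorical(feature, (person[m.person_id].gender_concept_id for m in memberships))
        elif feature == "race":
            categorical(feature, (person[m.person_id].race_concept_id for m in memberships))
        elif feature == "ethnicity":
            categorical(
                feature, (person[m.person_id].ethnicity_concept_id for m in memberships)
            )
        elif feature == "age_group":
            categorical(
                feature,
                (f"{int(a // 10) * 10}-{int(a // 10) * 10 + 9}" for a in ages()),
            )
        elif feature == "age_at_index":
            vals = list(ages())
            rows.append(
                {
                    "feature": feature,
                    "category": "mean",
                    "count": len(vals),
                    "proportion": None,
                    "mean": sum(vals) / len(vals) if vals else None,
                }
            )
        else:
            raise ValueError(f"unknown characterisation feature {feature!r}")
    return pd.DataFrame(rows, columns=["feature", "category", "count", "proportion", "mean"])


@dataclass(frozen=True)
class TimeAtRiskWindow:
    """Time-at-risk window as day offsets from the target index date
    (inclusive on both ends)."""

    start_offset_days: int = 0
    end_offset_days: int = 365


@dataclass(frozen=True)
class IncidenceRow:
    target_cohort: str
    outcome_cohort: str
    persons_at_risk: int
    cases: int
    person_years: float
    cases_per_1000_persons: Optional[float]
    rate_per_1000_py: Optional[float]  # None renders as n/a


def incidence_rates(
    cdm: CdmBundle,
    target_defns: Sequence[CohortDefinition],
    outcome_defn: CohortDefinition,
    window: TimeAtRiskWindow = TimeAtRiskWindow(),
) -> list[IncidenceRow]:
    """One incidence row per target cohort.

    A member is a case when their *earliest* outcome event falls inside the
    time-at-risk window; time at risk runs from window start to the outcome
    (censoring) or the window end, counted in inclusive days and converted
    to years at 365.25 days/year.
    """
    outcome_earliest: dict[int, dt.date] = {}
    for m in build_cohort(cdm, outcome_defn):
        outcome_earliest[m.person_id] = m.index_date

    out = []
    for defn in target_defns:
        members = build_cohort(cdm, defn)
        persons_at_risk = 0
        cases = 0
        total_days = 0
        for m in members:
            tar_start = m.index_date + dt.timedelta(days=window.start_offset_days)
            tar_end = m.index_date + dt.timedelta(days=window.end_offset_days)
            if tar_end < tar_start:
                continue
            persons_at_risk += 1
            outcome = outcome_earliest.get(m.person_id)
            if outcome is not None and tar_start <= outcome <= tar_end:
                cases += 1
                total_days += (outcome - tar_start).days + 1
            else:
                total_days += (tar_end - tar_start).days + 1
        person_years = total_days / 365.25
        out.append(
            IncidenceRow(
                target_cohort=defn.cohort_id,
                outcome_cohort=outcome_defn.cohort_id,
                persons_at_risk=persons_at_risk,
                cases=cases,
                person_years=person_years,
                cases_per_1000_persons=(
                    1000 * cases / persons_at_risk if persons_at_risk else None
                ),
                rate_per_1000_py=(1000 * cases / person_years if person_years > 0 else None),
            )
        )
    return out


def pathway_sequences(
    cdm: CdmBundle, event_defns: Sequence[CohortDefinition]
) -> dict[str, int]:
    """Chronological succession of first entries into each event cohort.

    Per person, the ordered sequence of first-entry cohorts; same-date first
    entries collapse to an unordered set rendered ``{A,B}``.  Returns
    distinct sequence -> person count; counts sum to the number of persons
    entering at least one cohort.
    """
    if len(event_defns) < 2:
        raise ValueError("pathway analysis needs at least two event cohort definitions")
    first_entry: dict[int, list[tuple[dt.date, str]]] = {}
    for defn in event_defns:
        for m in build_cohort(
            cdm,
            CohortDefinition(
                cohort_id=defn.cohort_id,
                domain=defn.domain,
                concept_ids=defn.concept_ids,
                min_value=defn.min_value,
                max_value=defn.max_value,
                restriction="earliest_event_only",
            ),
        ):
            first_entry.setdefault(m.person_id, []).append((m.index_date, defn.cohort_id))

    counts: dict[str, int] = {}
    for entries in first_entry.values():
        by_date: dict[dt.date, list[str]] = {}
        for date, cid in entries:
            by_date.setdefault(date, []).append(cid)
        parts = []
        for date in sorted(by_date):
            names = sorted(by_date[date])
            parts.append(names[0] if len(names) == 1 else "{" + ",".join(names) + "}")
        seq = "→".join(parts)
        counts[seq] = counts.get(seq, 0) + 1
    return counts
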