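"""Declarative data-quality checks over a CDM bundle (Kahn framework).

Checks are grouped by category — Conformance (structure: types, keys,
foreign keys, concept-domain and standard-flag agreement), Completeness
(mandatory fields populated) and Plausibility (values and dates in logically
possible ranges) — and by context: Verification checks test the CDM against
its own internal rules, Validation checks test it against the vocabulary
registry or externally declared expectations (e.g., demographic concept
membership).

Each check evaluates a row-level predicate, compares the violating fraction
against its threshold (default 0: any violation fails) and reports
PASS/FAIL, or NOT_APPLICABLE when no rows were evaluable.  The rollup table
mirrors the usual quality-dashboard shape: rows Plausibility / Conformance /
Completeness / Total crossed with Verification / Validation / Total, each
cell carrying pass, fail, total and % pass (whole percent).

This is a compact representative suite, not a re-implementation of the
1,500+ check catalogue of the OHDSI Data Quality Dashboard.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Callable, Optional

import pandas as pd

from .etl import CdmBundle
from .vocab import ConceptRegistry

__all__ = [
    "CheckDefinition",
    "CheckResult",
    "QualityReport",
    "QualityConfig",
    "RangeRule",
    "default_check_suite",
    "run_checks",
    "summarize_report",
    "quality_config_for",
]

CATEGORIES = ("Conformance", "Completeness", "Plausibility")
CONTEXTS = ("Verification", "Validation")


@dataclass(frozen=True)
class RangeRule:
    """Plausible closed range for a value field, scoped to concept ids."""

    table: str
    value_field: str
    concept_field: str
    concept_ids: tuple[int, ...]
    lo: float
    hi: float
    label: str


@dataclass(frozen=True)
class QualityConfig:
    reference_date: dt.date = dt.date(2024, 1, 1)
    range_rules: tuple[RangeRule, ...] = ()
    min_year_of_birth: int = 1850


@dataclass(frozen=True)
class CheckDefinition:
    check_id: str
    category: str
    context: str
    table: str
    field: Optional[str]
    predicate: str
    params: tuple = ()
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")


@dataclass(frozen=True)
class CheckResult:
    check_id: str
    category: str
    context: str
    rows_evaluated: int
    rows_violating: int
    status: str  # PASS | FAIL | NOT_APPLICABLE

    @property
    def violation_fraction(self) -> float:
        return 0.0 if self.rows_evaluated == 0 else self.rows_violating / self.rows_evaluated


@dataclass
class QualityReport:
    results: list[CheckResult] = field(default_factory=list)

    def result(self, check_id: str) -> CheckResult:
        for r in self.results:
            if r.check_id == check_id:
                return r
        raise KeyError(check_id)

    def pass_rate(self, category: Optional[str] = None, context: Optional[str] = None) -> float:
        """Pass fraction over applicable checks (NOT_APPLICABLE excluded)."""
        pool = [
            r
            for r in self.results
            if r.status != "NOT_APPLICABLE"
            and (category is None or r.category == category)
            and (context is None or r.context == context)
        ]
        if not pool:
            return float("nan")
        return sum(r.status == "PASS" for r in pool) / len(pool)


# ---------------------------------------------------------------------------
# predicates: (cdm, registry, config, defn) -> (rows_evaluated, rows_violating)

def _df(cdm: CdmBundle, table: str) -> pd.DataFrame:
    frames = cdm.tables()
    if table not in frames:
        raise ValueError(f"check references unknown table {table!r}")
    return frames[table]


def _p_not_null(cdm, registry, config, defn):
    df = _df(cdm, defn.table)
    col = df[defn.field]
    return len(df), int(sum(v is None for v in col))


def _p_unique(cdm, registry, config, defn):
    df = _df(cdm, defn.table)
    values = [v for v in df[defn.field] if v is not None]
    return len(values), len(values) - len(set(values))


def _p_cell_type(cdm, registry, config, defn):
    expected = {"int": int, "float": (int, float), "date": dt.date, "str": str}[defn.params[0]]
    df = _df(cdm, defn.table)
    values = [v for v in df[defn.field] if v is not None]
    return len(values), sum(not isinstance(v, expected) for v in values)


def _p_foreign_key(cdm, registry, config, defn):
    ref_table, ref_field = defn.params
    valid = set(v for v in _df(cdm, ref_table)[ref_field] if v is not None)
    values = [v for v in _df(cdm, defn.table)[defn.field] if v is not None]
    return len(values), sum(v not in valid for v in values)


def _p_concept_domain(cdm, registry, config, defn):
    (domain,) = defn.params
    values = [v for v in _df(cdm, defn.table)[defn.field] if v is not None and v != 0]
    bad = 0
    for v in values:
        c = registry.get(int(v))
        if c is None or c.domain_id != domain:
            bad += 1
    return len(values), bad


def _p_standard_concept(cdm, registry, config, defn):
    values = [v for v in _df(cdm, defn.table)[defn.field] if v is not None and v != 0]
    bad = 0
    for v in values:
        c = registry.get(int(v))
        if c is None or c.standard_flag != "S":
            bad += 1
    return len(values), bad


def _p_concept_membership(cdm, registry, config, defn):
    # validation: concept must exist in the registry within the given domain
    # (the unknown concept 0 is an accepted OMOP convention)
    return _p_concept_domain(cdm, registry, config, defn)


def _birth_dates(cdm) -> dict[int, dt.date]:
    out = {}
    for row in cdm.person.itertuples(index=False):
        if row.year_of_birth is None:
            continue
        out[row.person_id] = dt.date(
            int(row.year_of_birth),
            int(row.month_of_birth) if row.month_of_birth is not None else 7,
            int(row.day_of_birth) if row.day_of_birth is not None else 1,
        )
    return out


def _p_event_after_birth(cdm, registry, config, defn):
    births = _birth_dates(cdm)
    df = _df(cdm, defn.table)
    n = bad = 0
    for row in df.itertuples(index=False):
        date = getattr(row, defn.field)
        birth = births.get(row.person_id)
        if date is None or birth is None:
            continue
        n += 1
        if date < birth:
            bad += 1
    return n, bad


def _p_event_not_future(cdm, registry, config, defn):
    values = [v for v in _df(cdm, defn.table)[defn.field] if v is not None]
    return len(values), sum(v > config.reference_date for v in values)


def _p_start_le_end(cdm, registry, config, defn):
    start_field, end_field = defn.params
    df = _df(cdm, defn.table)
    n = bad = 0
    for row in df.itertuples(index=False):
        s, e = getattr(row, start_field), getattr(row, end_field)
        if s is None or e is None:
            continue
        n += 1
        if s > e:
            bad += 1
    return n, bad


def _p_year_of_birth_plausible(cdm, registry, config, defn):
    values = [v for v in cdm.person["year_of_birth"] if v is not None]
    lo, hi = config.min_year_of_birth, config.reference_date.year
    return len(values), sum(not (lo <= int(v) <= hi) for v in values)


def _p_value_range(cdm, registry, config, defn):
    (label,) = defn.params
    rule = next(r for r in config.range_rules if r.label == label)
    df = _df(cdm, rule.table)
    ids = set(rule.concept_ids)
    n = bad = 0
    for row in df.itertuples(index=False):
        if getattr(row, rule.concept_field) not in ids:
            continue
        v = getattr(row, rule.value_field)
        if v is None:
            continue
        n += 1
        if not (rule.lo <= v <= rule.hi):
            bad += 1
    return n, bad


PREDICATES: dict[str, Callable] = {
    "not_null": _p_not_null,
    "unique": _p_unique,
    "cell_type": _p_cell_type,
    "foreign_key": _p_foreign_key,
    "concept_domain": _p_concept_domain,
    "standard_concept": _p_standard_concept,
    "concept_membership": _p_concept_membership,
    "event_after_birth": _p_event_after_birth,
    "event_not_future": _p_event_not_future,
    "start_le_end": _p_start_le_end,
    "year_of_birth_plausible": _p_year_of_birth_plausible,
    "value_range": _p_value_range,
}


def default_check_suite(config: QualityConfig = QualityConfig()) -> list[CheckDefinition]:
    """The packaged representative check suite (>= 30 checks).

    Every CDM table carries at least one completeness check; concept-domain
    checks cover the measurement, observation and condition tables; the
    plausibility block covers date logic, the reference "today", and
    configured instrument value ranges.
    """
    checks: list[CheckDefinition] = []

    def add(check_id, category, context, table, field_, predicate, params=(), threshold=0.0):
        checks.append(
            CheckDefinition(check_id, category, context, table, field_, predicate, params, threshold)
        )

    # Completeness / Verification: mandatory fields populated
    for table, fields in {
        "location": ["location_id"],
        "person": ["person_id", "gender_concept_id", "year_of_birth"],
        "visit_occurrence": ["visit_occurrence_id", "person_id", "visit_concept_id"],
        "measurement": ["measurement_id", "person_id", "measurement_concept_id"],
        "observation": ["observation_id", "person_id", "observation_concept_id"],
        "condition_occurrence": [
            "condition_occurrence_id",
            "person_id",
            "condition_concept_id",
        ],
    }.items():
        for f in fields:
            add(f"completeness_not_null_{table}_{f}", "Completeness", "Verification", table, f, "not_null")

    # Conformance / Verification: keys, types, referential integrity
    for table, key in {
        "person": "person_id",
        "visit_occurrence": "visit_occurrence_id",
        "measurement": "measurement_id",
        "observation": "observation_id",
        "condition_occurrence": "condition_occurrence_id",
        "location": "location_id",
    }.items():
        add(f"conformance_unique_{table}_{key}", "Conformance", "Verification", table, key, "unique")
    for table in ("visit_occurrence", "measurement", "observation", "condition_occurrence"):
        add(
            f"conformance_fk_{table}_person_id",
            "Conformance",
            "Verification",
            table,
            "person_id",
            "foreign_key",
            ("person", "person_id"),
        )
    for table in ("measurement", "observation", "condition_occurrence"):
        add(
            f"conformance_fk_{table}_visit_occurrence_id",
            "Conformance",
            "Verification",
            table,
            "visit_occurrence_id",
            "foreign_key",
            ("visit_occurrence", "visit_occurrence_id"),
        )
    add(
        "conformance_fk_person_location_id",
        "Conformance",
        "Verification",
        "person",
        "location_id",
        "foreign_key",
        ("location", "location_id"),
    )
    for table, field_, kind in (
        ("person", "year_of_birth", "int"),
        ("visit_occurrence", "visit_start_date", "date"),
        ("measurement", "measurement_date", "date"),
        ("measurement", "value_as_number", "float"),
        ("observation", "observation_date", "date"),
        ("condition_occurrence", "condition_start_date", "date"),
    ):
        add(
            f"conformance_type_{table}_{field_}",
            "Conformance",
            "Verification",
            table,
            field_,
            "cell_type",
            (kind,),
        )

    # Conformance / Validation: concept-domain and standard-flag agreement
    for table, field_, domain in (
        ("measurement", "measurement_concept_id", "Measurement"),
        ("observation", "observation_concept_id", "Observation"),
        ("condition_occurrence", "condition_concept_id", "Condition"),
        ("visit_occurrence", "visit_concept_id", "Visit"),
    ):
        add(
            f"conformance_domain_{table}_{field_}",
            "Conformance",
            "Validation",
            table,
            field_,
            "concept_domain",
            (domain,),
        )
    for table, field_ in (
        ("measurement", "measurement_concept_id"),
        ("observation", "observation_concept_id"),
        ("condition_occurrence", "condition_concept_id"),
    ):
        add(
            f"conformance_standard_{table}_{field_}",
            "Conformance",
            "Validation",
            table,
            field_,
            "standard_concept",
        )

    # Plausibility / Verification: temporal logic and value ranges
    add(
        "plausibility_visit_start_le_end",
        "Plausibility",
        "Verification",
        "visit_occurrence",
        None,
        "start_le_end",
        ("visit_start_date", "visit_end_date"),
    )
    for table, field_ in (
        ("visit_occurrence", "visit_start_date"),
        ("measurement", "measurement_date"),
        ("observation", "observation_date"),
        ("condition_occurrence", "condition_start_date"),
    ):
        add(
            f"plausibility_after_birth_{table}",
            "Plausibility",
            "Verification",
            table,
            field_,
            "event_after_birth",
        )
        add(
            f"plausibility_not_future_{table}",
            "Plausibility",
            "Verification",
            table,
            field_,
            "event_not_future",
        )
    add(
        "plausibility_year_of_birth",
        "Plausibility",
        "Verification",
        "person",
        "year_of_birth",
        "year_of_birth_plausible",
    )
    for rule in config.range_rules:
        add(
            f"plausibility_range_{rule.label}",
            "Plausibility",
            "Verification",
            rule.table,
            rule.value_field,
            "value_range",
            (rule.label,),
        )

    # Plausibility / Validation: demographic concepts drawn from the registry
    for field_, domain in (
        ("gender_concept_id", "Gender"),
        ("race_concept_id", "Race"),
        ("ethnicity_concept_id", "Ethnicity"),
    ):
        add(
            f"validation_person_{field_}",
            "Plausibility",
            "Validation",
            "person",
            field_,
            "concept_membership",
            (domain,),
        )
    return checks


def run_checks(
    cdm: CdmBundle,
    registry: ConceptRegistry,
    suite: list[CheckDefinition],
    config: QualityConfig = QualityConfig(),
) -> QualityReport:
    """Execute a suite; fatal on a check referencing an unknown table."""
    known = set(cdm.tables())
    for defn in suite:
        if defn.table not in known:
            raise ValueError(f"check {defn.check_id} references unknown table {defn.table!r}")
        if defn.predicate not in PREDICATES:
            raise ValueError(f"check {defn.check_id} uses unknown predicate {defn.predicate!r}")
    report = QualityReport()
    for defn in suite:
        evaluated, violating = PREDICATES[defn.predicate](cdm, registry, config, defn)
        if evaluated == 0:
            status = "NOT_APPLICABLE"
        else:
            status = "PASS" if violating / evaluated <= defn.threshold else "FAIL"
        report.results.append(
            CheckResult(
                check_id=defn.check_id,
                category=defn.category,
                context=defn.context,
                rows_evaluated=evaluated,
                rows_violating=violating,
                status=status,
            )
        )
    return report


def summarize_report(report: QualityReport) -> pd.DataFrame:
    """Category x context rollup: pass / fail / total / % pass (whole percent).

    NOT_APPLICABLE results are excluded from every denominator; a cell with
    no applicable checks renders % pass as blank.
    """
    rows = []
    for category in ("Plausibility", "Conformance", "Completeness", "Total"):
        rec: dict = {"category": category}
        for context in ("Verification", "Validation", "Total"):
            pool = [
                r
                for r in report.results
                if r.status != "NOT_APPLICABLE"
                and (category == "Total" or r.category == category)
                and (context == "Total" or r.context == context)
            ]
            npass = sum(r.status == "PASS" for r in pool)
            nfail = len(pool) - npass
            rec[f"{context.lower()}_pass"] = npass
            rec[f"{context.lower()}_fail"] = nfail
            rec[f"{context.lower()}_total"] = len(pool)
            rec[f"{context.lower()}_pct_pass"] = (
                "" if not pool else f"{round(100 * npass / len(pool))}%"
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def quality_config_for(
    plan, bundle, etl_config, *, reference_date: Optional[dt.date] = None
) -> QualityConfig:
    """Derive range rules (instrument items and composite scores) from a
    mapping plan plus the staging variable metadata."""
    from .instruments import STANDARD_INSTRUMENTS

    rules: list[RangeRule] = []
    by_instrument: dict[str, list[int]] = {}
    for var in bundle.variables:
        if var.instrument_id is None or var.instrument_id not in STANDARD_INSTRUMENTS:
            continue
        entry = plan.entries.get(var.variable_id)
        if entry is None:
            continue
        by_instrument.setdefault(var.instrument_id, []).append(entry.target_concept_id)
    for inst, concept_ids in sorted(by_instrument.items()):
        defn = STANDARD_INSTRUMENTS[inst]
        lo, hi = defn.item_range
        rules.append(
            RangeRule(
                table="observation",
                value_field="value_as_number",
                concept_field="observation_concept_id",
                concept_ids=tuple(concept_ids),
                lo=lo,
                hi=hi,
                label=f"{inst}_items",
            )
        )
    for inst, concept_id in etl_config.score_concepts:
        defn = STANDARD_INSTRUMENTS[inst]
        lo, hi = defn.score_range
        rules.append(
            RangeRule(
                table="measurement",
                value_field="value_as_number",
                concept_field="measurement_concept_id",
                concept_ids=(concept_id,),
                lo=lo,
                hi=hi,
                label=f"{inst}_total",
            )
        )
    return QualityConfig(
        reference_date=reference_date or etl_config.reference_date,
        range_rules=tuple(rules),
    )
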