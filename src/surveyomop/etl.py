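"""Dependency-ordered staging -> OMOP CDM transformation with a full audit trail.

Tables are populated in dependency order (location -> care_site/provider ->
person -> visit_occurrence -> measurement / observation /
condition_occurrence).  One visit_occurrence is created per (person, wave)
with at least one response; item responses are emitted to the domain the
mapping plan routes them to (Observation by default), and instrument
composite scores to Measurement.  Condition rows come from explicit
score-threshold rules or from variables mapped to the Condition domain.

Cleaning follows an exclude-or-null-and-log posture:

* a NULL required identifier excludes the row — placeholder identifiers are
  never invented;
* a birth date after the configured reference date is nulled, after which
  the person fails the year-of-birth requirement and is excluded;
* an event date preceding the person's birth date is nulled;
* a present-but-unmappable demographic code is remapped to the
  "no matching concept" concept (id 0); an *absent* code is defaulted to 0
  silently (that is the normal OMOP convention, not an error).

Every exclusion or nulling writes exactly one ``etl_error_log`` row, and
every step writes an ``etl_execution_summary`` row with
``rows_in = rows_out + rows_excluded``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .instruments import STANDARD_INSTRUMENTS, get_instrument, wave_scores
from .mapping import MappingPlan
from .staging import StagingBundle
from .vocab import ConceptRegistry

__all__ = [
    "EtlConfig",
    "ConditionRule",
    "EtlError",
    "CdmBundle",
    "run_etl",
    "clean_dates",
    "apply_demographic_defaults",
    "write_cdm",
    "load_cdm",
    "CDM_SCHEMAS",
    "DEFAULT_REFERENCE_DATE",
]

DEFAULT_REFERENCE_DATE = dt.date(2024, 1, 1)
UNKNOWN_CONCEPT_ID = 0


class EtlError(RuntimeError):
    """Unrecoverable ETL configuration/reference problem (raised before writes)."""


@dataclass(frozen=True)
class ConditionRule:
    """Emit a condition_occurrence when an instrument total reaches a cut-point."""

    instrument_id: str
    min_score: int
    condition_concept_id: int


@dataclass(frozen=True)
class EtlConfig:
    reference_date: dt.date = DEFAULT_REFERENCE_DATE
    survey_type_concept_id: int = 32862  # "Patient filled survey"
    visit_concept_id: int = 581477  # "Home Visit"
    unknown_concept_id: int = UNKNOWN_CONCEPT_ID
    sex_code_map: tuple[tuple[str, int], ...] = (("F", 8532), ("M", 8507))
    race_code_map: tuple[tuple[str, int], ...] = (("R1", 8516), ("R2", 8527), ("R3", 8522))
    ethnicity_code_map: tuple[tuple[str, int], ...] = (
        ("E1", 38003563),
        ("E2", 38003564),
    )
    score_concepts: tuple[tuple[str, int], ...] = ()  # instrument -> Measurement concept
    condition_rules: tuple[ConditionRule, ...] = ()
    prorate_scores: bool = False

    def score_concept_map(self) -> dict[str, int]:
        return dict(self.score_concepts)


# column order and cell type per CDM table ("int" columns are nullable)
CDM_SCHEMAS: dict[str, list[tuple[str, str]]] = {
    "location": [
        ("location_id", "int"),
        ("address_1", "str"),
        ("latitude", "float"),
        ("longitude", "float"),
        ("location_source_value", "str"),
    ],
    "care_site": [
        ("care_site_id", "int"),
        ("care_site_name", "str"),
        ("location_id", "int"),
    ],
    "provider": [
        ("provider_id", "int"),
        ("provider_name", "str"),
        ("care_site_id", "int"),
    ],
    "person": [
        ("person_id", "int"),
        ("gender_concept_id", "int"),
        ("year_of_birth", "int"),
        ("month_of_birth", "int"),
        ("day_of_birth", "int"),
        ("race_concept_id", "int"),
        ("ethnicity_concept_id", "int"),
        ("location_id", "int"),
        ("person_source_value", "str"),
        ("gender_source_value", "str"),
        ("race_source_value", "str"),
        ("ethnicity_source_value", "str"),
    ],
    "visit_occurrence": [
        ("visit_occurrence_id", "int"),
        ("person_id", "int"),
        ("visit_concept_id", "int"),
        ("visit_start_date", "date"),
        ("visit_end_date", "date"),
        ("visit_type_concept_id", "int"),
        ("visit_source_value", "str"),
    ],
    "measurement": [
        ("measurement_id", "int"),
        ("person_id", "int"),
        ("measurement_concept_id", "int"),
        ("measurement_date", "date"),
        ("measurement_type_concept_id", "int"),
        ("value_as_number", "float"),
        ("value_as_concept_id", "int"),
        ("unit_concept_id", "int"),
        ("visit_occurrence_id", "int"),
        ("measurement_source_value", "str"),
    ],
    "observation": [
        ("observation_id", "int"),
        ("person_id", "int"),
        ("observation_concept_id", "int"),
        ("observation_date", "date"),
        ("observation_type_concept_id", "int"),
        ("value_as_number", "float"),
        ("value_as_concept_id", "int"),
        ("value_as_string", "str"),
        ("visit_occurrence_id", "int"),
        ("observation_source_value", "str"),
    ],
    "condition_occurrence": [
        ("condition_occurrence_id", "int"),
        ("person_id", "int"),
        ("condition_concept_id", "int"),
        ("condition_start_date", "date"),
        ("condition_type_concept_id", "int"),
        ("visit_occurrence_id", "int"),
        ("condition_source_value", "str"),
    ],
    "etl_error_log": [
        ("step", "str"),
        ("table_name", "str"),
        ("row_key", "str"),
        ("rule", "str"),
        ("action", "str"),
    ],
    "etl_execution_summary": [
        ("step", "str"),
        ("rows_in", "int"),
        ("rows_out", "int"),
        ("rows_excluded", "int"),
    ],
}

EVENT_TABLES = {
    "visit_occurrence": ["visit_start_date", "visit_end_date"],
    "measurement": ["measurement_date"],
    "observation": ["observation_date"],
    "condition_occurrence": ["condition_start_date"],
}


def _empty_table(name: str) -> pd.DataFrame:
    return pd.DataFrame({col: pd.Series(dtype=object) for col, _ in CDM_SCHEMAS[name]})


def _table(name: str, rows: list[dict]) -> pd.DataFrame:
    cols = [c for c, _ in CDM_SCHEMAS[name]]
    if not rows:
        return _empty_table(name)
    return pd.DataFrame(rows, columns=cols).astype(object).where(pd.notna, None)


@dataclass
class CdmBundle:
    location: pd.DataFrame = field(default_factory=lambda: _empty_table("location"))
    care_site: pd.DataFrame = field(default_factory=lambda: _empty_table("care_site"))
    provider: pd.DataFrame = field(default_factory=lambda: _empty_table("provider"))
    person: pd.DataFrame = field(default_factory=lambda: _empty_table("person"))
    visit_occurrence: pd.DataFrame = field(
        default_factory=lambda: _empty_table("visit_occurrence")
    )
    measurement: pd.DataFrame = field(default_factory=lambda: _empty_table("measurement"))
    observation: pd.DataFrame = field(default_factory=lambda: _empty_table("observation"))
    condition_occurrence: pd.DataFrame = field(
        default_factory=lambda: _empty_table("condition_occurrence")
    )
    error_log: pd.DataFrame = field(default_factory=lambda: _empty_table("etl_error_log"))
    execution_summary: pd.DataFrame = field(
        default_factory=lambda: _empty_table("etl_execution_summary")
    )

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "location": self.location,
            "care_site": self.care_site,
            "provider": self.provider,
            "person": self.person,
            "visit_occurrence": self.visit_occurrence,
            "measurement": self.measurement,
            "observation": self.observation,
            "condition_occurrence": self.condition_occurrence,
            "etl_error_log": self.error_log,
            "etl_execution_summary": self.execution_summary,
        }

    def event_tables(self) -> dict[str, pd.DataFrame]:
        return {
            "visit_occurrence": self.visit_occurrence,
            "measurement": self.measurement,
            "observation": self.observation,
            "condition_occurrence": self.condition_occurrence,
        }


class _Audit:
    """Collects etl_error_log and etl_execution_summary rows."""

    def __init__(self) -> None:
        self.errors: list[dict] = []
        self.steps: list[dict] = []

    def log(self, step: str, table: str, row_key: str, rule: str, action: str) -> None:
        self.errors.append(
            {"step": step, "table_name": table, "row_key": row_key, "rule": rule, "action": action}
        )

    def step(self, step: str, rows_in: int, rows_out: int) -> None:
        self.steps.append(
            {
                "step": step,
                "rows_in": rows_in,
                "rows_out": rows_out,
                "rows_excluded": rows_in - rows_out,
            }
        )


def clean_dates(
    rows: list[dict],
    date_fields: list[str],
    birth_by_person: dict[int, Optional[dt.date]],
    *,
    table: str,
    step: str,
    audit: _Audit,
    row_key_field: str = "row_key",
) -> None:
    """Null (in place) event dates preceding the person's birth date, logging
    one entry per affected row."""
    n = len(rows)
    for row in rows:
        birth = birth_by_person.get(row["person_id"])
        if birth is None:
            continue
        hit = False
        for f in date_fields:
            if row.get(f) is not None and row[f] < birth:
                row[f] = None
                hit = True
        if hit:
            audit.log(step, table, str(row.get(row_key_field, "")), "event_before_birth", "nulled")
    audit.step(step, n, n)


def apply_demographic_defaults(
    rows: list[dict], config: EtlConfig, *, audit: _Audit, step: str = "apply_demographic_defaults"
) -> int:
    """COALESCE-style demographic defaulting (in place).

    Absent codes take the configured unknown concept (0) silently; codes
    that are present but have no mapping are remapped to 0 *and* logged as
    data errors.  Returns the number of silent replacements.
    """
    maps = {
        "gender": dict(config.sex_code_map),
        "race": dict(config.race_code_map),
        "ethnicity": dict(config.ethnicity_code_map),
    }
    replaced = 0
    for row in rows:
        for field_stub in ("gender", "race", "ethnicity"):
            code = row.get(f"{field_stub}_source_value")
            target = f"{field_stub}_concept_id"
            if code is None or code == "":
                row[target] = config.unknown_concept_id
                replaced += 1
            elif code in maps[field_stub]:
                row[target] = maps[field_stub][code]
            else:
                row[target] = config.unknown_concept_id
                audit.log(
                    step,
                    "person",
                    str(row["person_source_value"]),
                    "unmapped_demographic_code",
                    "remapped",
                )
    audit.step(step, len(rows), len(rows))
    return replaced


def _validate_plan(plan: MappingPlan, registry: ConceptRegistry, config: EtlConfig) -> None:
    for entry in plan.entries.values():
        if entry.target_concept_id not in registry:
            raise EtlError(
                f"mapping plan references unknown concept {entry.target_concept_id} "
                f"for variable {entry.variable_id}"
            )
        for concept_id in entry.value_map.values():
            if concept_id not in registry:
                raise EtlError(f"value map references unknown concept {concept_id}")
    for inst, concept_id in config.score_concepts:
        if concept_id not in registry:
            raise EtlError(f"score concept {concept_id} for {inst} not in registry")
    for rule in config.condition_rules:
        if rule.condition_concept_id not in registry:
            raise EtlError(f"condition rule concept {rule.condition_concept_id} not in registry")


def run_etl(
    bundle: StagingBundle,
    plan: MappingPlan,
    registry: ConceptRegistry,
    config: EtlConfig = EtlConfig(),
) -> CdmBundle:
    """Transform a staging bundle into a CDM bundle under a mapping plan."""
    _validate_plan(plan, registry, config)
    audit = _Audit()
    ref = config.reference_date
    unmapped_vars = {e.variable_id for e in plan.review_queue}

    # ---- location (from households) ------------------------------------
    loc_rows = []
    location_by_household: dict[str, int] = {}
    for k, hh in enumerate(sorted(bundle.households, key=lambda h: h.household_id)):
        location_by_household[hh.household_id] = k + 1
        loc_rows.append(
            {
                "location_id": k + 1,
                "address_1": hh.location_label,
                "latitude": hh.latitude,
                "longitude": hh.longitude,
                "location_source_value": hh.household_id,
            }
        )
    audit.step("build_location", len(bundle.households), len(loc_rows))

    # ---- person ---------------------------------------------------------
    individuals = list(bundle.individuals)
    retained = []
    for i, ind in enumerate(individuals):
        if ind.individual_id in (None, ""):
            audit.log("extract_persons", "person", f"individuals_row_{i}", "null_person_id", "excluded")
        else:
            retained.append(ind)
    audit.step("extract_persons", len(individuals), len(retained))

    person_rows = []
    person_id_by_source: dict[str, int] = {}
    for k, ind in enumerate(sorted(retained, key=lambda x: x.individual_id)):
        person_id_by_source[ind.individual_id] = k + 1
        person_rows.append(
            {
                "person_id": k + 1,
                "gender_concept_id": None,
                "year_of_birth": ind.birth_date.year if ind.birth_date else None,
                "month_of_birth": ind.birth_date.month if ind.birth_date else None,
                "day_of_birth": ind.birth_date.day if ind.birth_date else None,
                "race_concept_id": None,
                "ethnicity_concept_id": None,
                "location_id": location_by_household.get(ind.household_id),
                "person_source_value": ind.individual_id,
                "gender_source_value": ind.sex_code,
                "race_source_value": ind.race_code,
                "ethnicity_source_value": ind.ethnicity_code,
                "_birth_date": ind.birth_date,
            }
        )

    # null future birth dates (logical-consistency cleaning)
    for row in person_rows:
        b = row["_birth_date"]
        if b is not None and b > ref:
            row["_birth_date"] = None
            row["year_of_birth"] = row["month_of_birth"] = row["day_of_birth"] = None
            audit.log(
                "clean_birth_dates", "person", row["person_source_value"], "future_birth_date", "nulled"
            )
    audit.step("clean_birth_dates", len(person_rows), len(person_rows))

    # year_of_birth is required: exclude, never fabricate
    kept_rows = []
    for row in person_rows:
        if row["year_of_birth"] is None:
            audit.log(
                "require_year_of_birth",
                "person",
                row["person_source_value"],
                "missing_year_of_birth",
                "excluded",
            )
            del person_id_by_source[row["person_source_value"]]
        else:
            kept_rows.append(row)
    audit.step("require_year_of_birth", len(person_rows), len(kept_rows))
    person_rows = kept_rows

    apply_demographic_defaults(person_rows, config, audit=audit)

    birth_by_person: dict[int, Optional[dt.date]] = {
        row["person_id"]: row["_birth_date"] for row in person_rows
    }
    for row in person_rows:
        del row["_birth_date"]

    # ---- visit_occurrence: one per (person, wave) with any response -----
    wave_by_id = {w.wave_id: w for w in bundle.waves}
    pair_seen: dict[tuple[str, str], None] = {}
    for r in bundle.responses:
        pair_seen.setdefault((r.individual_id, r.wave_id), None)
    pairs = list(pair_seen)

    visit_rows = []
    visit_id_by_pair: dict[tuple[str, str], int] = {}
    dangling_pairs: set[tuple[str, str]] = set()
    ordered = sorted(
        pairs, key=lambda p: (person_id_by_source.get(p[0], 0), wave_by_id[p[1]].wave_index)
    )
    for iid, wid in ordered:
        pid = person_id_by_source.get(iid)
        if pid is None:
            dangling_pairs.add((iid, wid))
            audit.log(
                "build_visits",
                "visit_occurrence",
                f"{iid}|{wid}",
                "dangling_person_reference",
                "excluded",
            )
            continue
        vid = len(visit_rows) + 1
        visit_id_by_pair[(iid, wid)] = vid
        wdate = wave_by_id[wid].wave_date
        visit_rows.append(
            {
                "visit_occurrence_id": vid,
                "person_id": pid,
                "visit_concept_id": config.visit_concept_id,
                "visit_start_date": wdate,
                "visit_end_date": wdate,
                "visit_type_concept_id": config.survey_type_concept_id,
                "visit_source_value": f"{iid}|{wid}",
                "row_key": f"{iid}|{wid}",
            }
        )
    audit.step("build_visits", len(pairs), len(visit_rows))
    clean_dates(
        visit_rows,
        ["visit_start_date", "visit_end_date"],
        birth_by_person,
        table="visit_occurrence",
        step="clean_visit_dates",
        audit=audit,
    )

    # ---- composite scores -> measurement --------------------------------
    score_concepts = config.score_concept_map()
    item_range_by_var = {}
    for var in bundle.variables:
        if var.instrument_id is not None and var.instrument_id in STANDARD_INSTRUMENTS:
            item_range_by_var[var.variable_id] = get_instrument(var.instrument_id).item_range

    scoring_input = bundle.copy()
    scoring_input.responses = [
        r
        for r in bundle.responses
        if r.individual_id in person_id_by_source
        and not (
            r.variable_id in item_range_by_var
            and r.numeric_value is not None
            and not (
                item_range_by_var[r.variable_id][0]
                <= r.numeric_value
                <= item_range_by_var[r.variable_id][1]
            )
        )
    ]
    scores = wave_scores(scoring_input, prorate=config.prorate_scores)

    meas_rows = []
    score_by_pair_inst: dict[tuple[str, str, str], int] = {}
    for (iid, wid, inst), result in sorted(
        scores.items(), key=lambda kv: (person_id_by_source[kv[0][0]], wave_by_id[kv[0][1]].wave_index, kv[0][2])
    ):
        if result.total is None or inst not in score_concepts:
            continue
        score_by_pair_inst[(iid, wid, inst)] = result.total
        mid = len(meas_rows) + 1
        meas_rows.append(
            {
                "measurement_id": mid,
                "person_id": person_id_by_source[iid],
                "measurement_concept_id": score_concepts[inst],
                "measurement_date": wave_by_id[wid].wave_date,
                "measurement_type_concept_id": config.survey_type_concept_id,
                "value_as_number": float(result.total),
                "value_as_concept_id": None,
                "unit_concept_id": None,
                "visit_occurrence_id": visit_id_by_pair.get((iid, wid)),
                "measurement_source_value": f"{iid}|{wid}|{inst}",
                "row_key": f"{iid}|{wid}|{inst}",
            }
        )
    audit.step("build_measurements", len(meas_rows), len(meas_rows))

    # ---- item responses & covariates -> observation (default routing) ---
    obs_rows = []
    cond_response_rows = []
    meas_response_rows = []
    for j, r in enumerate(bundle.responses):
        pid = person_id_by_source.get(r.individual_id)
        key = f"{r.individual_id}|{r.wave_id}|{r.variable_id}"
        if pid is None:
            audit.log(
                "build_observations", "observation", key, "dangling_person_reference", "excluded"
            )
            continue
        if r.variable_id in unmapped_vars or r.variable_id not in plan.entries:
            audit.log("build_observations", "observation", key, "unmapped_variable", "excluded")
            continue
        entry = plan.entries[r.variable_id]
        wdate = wave_by_id[r.wave_id].wave_date
        vid = visit_id_by_pair.get((r.individual_id, r.wave_id))
        if entry.target_domain == "Condition":
            cond_response_rows.append((pid, entry.target_concept_id, wdate, vid, key))
            continue
        value_concept = entry.value_map.get(r.raw_value)
        if entry.target_domain == "Measurement":
            meas_response_rows.append(
                {
                    "person_id": pid,
                    "measurement_concept_id": entry.target_concept_id,
                    "measurement_date": wdate,
                    "measurement_type_concept_id": config.survey_type_concept_id,
                    "value_as_number": r.numeric_value,
                    "value_as_concept_id": value_concept,
                    "unit_concept_id": entry.unit_concept,
                    "visit_occurrence_id": vid,
                    "measurement_source_value": key,
                    "row_key": key,
                }
            )
            continue
        obs_rows.append(
            {
                "observation_id": len(obs_rows) + 1,
                "person_id": pid,
                "observation_concept_id": entry.target_concept_id,
                "observation_date": wdate,
                "observation_type_concept_id": config.survey_type_concept_id,
                "value_as_number": r.numeric_value,
                "value_as_concept_id": value_concept,
                "value_as_string": r.raw_value if value_concept is None else None,
                "visit_occurrence_id": vid,
                "observation_source_value": key,
                "row_key": key,
            }
        )
    audit.step(
        "build_observations",
        len(bundle.responses),
        len(obs_rows) + len(cond_response_rows) + len(meas_response_rows),
    )
    for row in meas_response_rows:
        row["measurement_id"] = len(meas_rows) + 1
        meas_rows.append(row)
    clean_dates(
        meas_rows,
        ["measurement_date"],
        birth_by_person,
        table="measurement",
        step="clean_measurement_dates",
        audit=audit,
    )
    clean_dates(
        obs_rows,
        ["observation_date"],
        birth_by_person,
        table="observation",
        step="clean_observation_dates",
        audit=audit,
    )

    # ---- condition_occurrence -------------------------------------------
    cond_rows = []
    for pid, concept_id, wdate, vid, key in cond_response_rows:
        cond_rows.append(
            {
                "condition_occurrence_id": len(cond_rows) + 1,
                "person_id": pid,
                "condition_concept_id": concept_id,
                "condition_start_date": wdate,
                "condition_type_concept_id": config.survey_type_concept_id,
                "visit_occurrence_id": vid,
                "condition_source_value": key,
                "row_key": key,
            }
        )
    for rule in config.condition_rules:
        for (iid, wid, inst), total in score_by_pair_inst.items():
            if inst == rule.instrument_id and total >= rule.min_score:
                key = f"{iid}|{wid}|{inst}>= {rule.min_score}"
                cond_rows.append(
                    {
                        "condition_occurrence_id": len(cond_rows) + 1,
                        "person_id": person_id_by_source[iid],
                        "condition_concept_id": rule.condition_concept_id,
                        "condition_start_date": wave_by_id[wid].wave_date,
                        "condition_type_concept_id": config.survey_type_concept_id,
                        "visit_occurrence_id": visit_id_by_pair.get((iid, wid)),
                        "condition_source_value": key,
                        "row_key": key,
                    }
                )
    audit.step("build_conditions", len(cond_rows), len(cond_rows))
    clean_dates(
        cond_rows,
        ["condition_start_date"],
        birth_by_person,
        table="condition_occurrence",
        step="clean_condition_dates",
        audit=audit,
    )

    for rows in (visit_rows, meas_rows, obs_rows, cond_rows):
        for row in rows:
            row.pop("row_key", None)

    return CdmBundle(
        location=_table("location", loc_rows),
        care_site=_empty_table("care_site"),
        provider=_empty_table("provider"),
        person=_table("person", person_rows),
        visit_occurrence=_table("visit_occurrence", visit_rows),
        measurement=_table("measurement", meas_rows),
        observation=_table("observation", obs_rows),
        condition_occurrence=_table("condition_occurrence", cond_rows),
        error_log=_table("etl_error_log", audit.errors),
        execution_summary=_table("etl_execution_summary", audit.steps),
    )


# ---------------------------------------------------------------------------
# CSV round trip: lowercase OMOP column names, ISO-8601 dates, '' = NULL

def _format_cell(value, kind: str) -> str:
    if value is None:
        return ""
    if kind == "date":
        return value.isoformat()
    if kind == "float":
        return repr(float(value))
    if kind == "int":
        return str(int(value))
    return str(value)


def _parse_cell(text: str, kind: str):
    if text == "":
        return None
    if kind == "date":
        return dt.date.fromisoformat(text)
    if kind == "float":
        return float(text)
    if kind == "int":
        return int(text)
    return text


def write_cdm(cdm: CdmBundle, path) -> dict[str, Path]:
    """One CSV per CDM table (plus error log and execution summary)."""
    import csv as _csv

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, df in cdm.tables().items():
        schema = CDM_SCHEMAS[name]
        fp = path / f"{name}.csv"
        with open(fp, "w", newline="", encoding="utf-8") as fh:
            writer = _csv.writer(fh, lineterminator="\n")
            writer.writerow([c for c, _ in schema])
            for row in df.itertuples(index=False):
                writer.writerow(
                    [_format_cell(v, kind) for v, (_, kind) in zip(row, schema)]
                )
        manifest[name] = fp
    return manifest


def load_cdm(path) -> CdmBundle:
    import csv as _csv

    path = Path(path)
    frames: dict[str, pd.DataFrame] = {}
    for name, schema in CDM_SCHEMAS.items():
        fp = path / f"{name}.csv"
        if not fp.exists():
            raise EtlError(f"missing CDM table file: {fp}")
        with open(fp, newline="", encoding="utf-8") as fh:
            reader = _csv.reader(fh)
            header = next(reader, None)
            if header != [c for c, _ in schema]:
                raise EtlError(f"{fp}: malformed header {header!r}")
            rows = [
                {col: _parse_cell(cell, kind) for cell, (col, kind) in zip(row, schema)}
                for row in reader
            ]
        frames[name] = _table(name, rows)
    return CdmBundle(
        location=frames["location"],
        care_site=frames["care_site"],
        provider=frames["provider"],
        person=frames["person"],
        visit_occurrence=frames["visit_occurrence"],
        measurement=frames["measurement"],
        observation=frames["observation"],
        condition_occurrence=frames["condition_occurrence"],
        error_log=frames["etl_error_log"],
        execution_summary=frames["etl_execution_summary"],
    )
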