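"""Snowflake-schema staging model for multi-study longitudinal survey data.

The staging layer holds households, individuals, data-collection waves,
variable (item) definitions and item responses for one study, prior to
transformation into the OMOP CDM.  It is file-backed: one UTF-8 CSV per
table with a fixed header, ISO-8601 dates, and the empty string meaning
"absent".  Reads are validating: rows whose references do not resolve are
excluded and counted, never repaired.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = [
    "StagingError",
    "StagingHousehold",
    "StagingIndividual",
    "StagingWave",
    "StagingVariable",
    "StagingResponse",
    "StagingBundle",
    "load_staging",
    "write_staging",
    "TABLE_COLUMNS",
]


class StagingError(ValueError):
    """Fatal problem with a staging directory (missing table, bad header)."""


VALUE_KINDS = ("quantitative", "categorical", "free_text")

TABLE_COLUMNS = {
    "households": ["household_id", "location_label", "latitude", "longitude"],
    "individuals": [
        "individual_id",
        "household_id",
        "sex_code",
        "birth_date",
        "race_code",
        "ethnicity_code",
        "marital_status_code",
    ],
    "waves": ["wave_id", "study_id", "wave_index", "wave_date"],
    "variables": [
        "variable_id",
        "instrument_id",
        "value_kind",
        "unit_label",
        "allowed_values",
        "is_diagnosis",
    ],
    "responses": ["individual_id", "wave_id", "variable_id", "raw_value", "numeric_value"],
}


@dataclass(frozen=True)
class StagingHousehold:
    household_id: str
    location_label: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None


@dataclass(frozen=True)
class StagingIndividual:
    individual_id: str
    household_id: Optional[str] = None
    sex_code: Optional[str] = None
    birth_date: Optional[dt.date] = None
    race_code: Optional[str] = None
    ethnicity_code: Optional[str] = None
    marital_status_code: Optional[str] = None


@dataclass(frozen=True)
class StagingWave:
    wave_id: str
    study_id: str
    wave_index: int
    wave_date: dt.date


@dataclass(frozen=True)
class StagingVariable:
    variable_id: str
    instrument_id: Optional[str] = None  # None => non-instrument covariate
    value_kind: str = "categorical"
    unit_label: Optional[str] = None
    allowed_values: Optional[tuple[str, ...]] = None
    is_diagnosis: bool = False

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise StagingError(f"unknown value_kind {self.value_kind!r}")


@dataclass(frozen=True)
class StagingResponse:
    individual_id: str
    wave_id: str
    variable_id: str
    raw_value: str
    numeric_value: Optional[float] = None


@dataclass
class StagingBundle:
    """One study's staging tables; referentially closed after validation."""

    study_id: str
    households: list[StagingHousehold] = field(default_factory=list)
    individuals: list[StagingIndividual] = field(default_factory=list)
    waves: list[StagingWave] = field(default_factory=list)
    variables: list[StagingVariable] = field(default_factory=list)
    responses: list[StagingResponse] = field(default_factory=list)
    # per-table dangling-reference exclusion counts from the last load;
    # metadata, not data: excluded from equality so round trips compare clean
    exclusions: dict = field(default_factory=dict, compare=False)

    def validate_references(self) -> "StagingBundle":
        """Return a referentially closed copy, recording exclusion counts."""
        excl: dict[str, int] = {}
        hh_ids = {h.household_id for h in self.households}
        individuals = []
        n = 0
        for ind in self.individuals:
            if ind.household_id is not None and ind.household_id not in hh_ids:
                n += 1
            else:
                individuals.append(ind)
        if n:
            excl["individuals"] = n
        ind_ids = {i.individual_id for i in individuals}
        wave_ids = {w.wave_id for w in self.waves}
        var_ids = {v.variable_id for v in self.variables}
        responses = []
        n = 0
        for r in self.responses:
            if (
                r.individual_id in ind_ids
                and r.wave_id in wave_ids
                and r.variable_id in var_ids
            ):
                responses.append(r)
            else:
                n += 1
        if n:
            excl["responses"] = n
        return StagingBundle(
            study_id=self.study_id,
            households=list(self.households),
            individuals=individuals,
            waves=list(self.waves),
            variables=list(self.variables),
            responses=responses,
            exclusions=excl,
        )

    def copy(self) -> "StagingBundle":
        return StagingBundle(
            study_id=self.study_id,
            households=list(self.households),
            individuals=list(self.individuals),
            waves=list(self.waves),
            variables=list(self.variables),
            responses=list(self.responses),
            exclusions=dict(self.exclusions),
        )


# ---------------------------------------------------------------------------
# serialisation helpers: '' <-> None, ISO dates, repr-exact floats

def _s(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, dt.date):
        return value.isoformat()
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _opt_str(text: str) -> Optional[str]:
    return text if text != "" else None


def _opt_float(text: str) -> Optional[float]:
    return float(text) if text != "" else None


def _opt_date(text: str) -> Optional[dt.date]:
    return dt.date.fromisoformat(text) if text != "" else None


def _read_table(path: Path, name: str) -> list[dict]:
    fp = path / f"{name}.csv"
    if not fp.exists():
        raise StagingError(f"missing staging table file: {fp}")
    with open(fp, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise StagingError(f"{fp}: empty file, expected header row") from None
        if header != TABLE_COLUMNS[name]:
            raise StagingError(
                f"{fp}: malformed header {header!r}, expected {TABLE_COLUMNS[name]!r}"
            )
        return [dict(zip(header, row)) for row in reader]


def load_staging(path, study_id: str) -> StagingBundle:
    """Read one study's staging tables from ``path``.

    Rows with dangling references are excluded; per-table counts land in
    ``bundle.exclusions``.  Missing files and malformed headers raise
    :class:`StagingError`.
    """
    path = Path(path)
    households = [
        StagingHousehold(
            household_id=r["household_id"],
            location_label=r["location_label"],
            latitude=_opt_float(r["latitude"]),
            longitude=_opt_float(r["longitude"]),
        )
        for r in _read_table(path, "households")
    ]
    individuals = [
        StagingIndividual(
            individual_id=r["individual_id"],
            household_id=_opt_str(r["household_id"]),
            sex_code=_opt_str(r["sex_code"]),
            birth_date=_opt_date(r["birth_date"]),
            race_code=_opt_str(r["race_code"]),
            ethnicity_code=_opt_str(r["ethnicity_code"]),
            marital_status_code=_opt_str(r["marital_status_code"]),
        )
        for r in _read_table(path, "individuals")
    ]
    waves = [
        StagingWave(
            wave_id=r["wave_id"],
            study_id=r["study_id"],
            wave_index=int(r["wave_index"]),
            wave_date=dt.date.fromisoformat(r["wave_date"]),
        )
        for r in _read_table(path, "waves")
    ]
    variables = [
        StagingVariable(
            variable_id=r["variable_id"],
            instrument_id=_opt_str(r["instrument_id"]),
            value_kind=r["value_kind"],
            unit_label=_opt_str(r["unit_label"]),
            allowed_values=(
                tuple(r["allowed_values"].split("|")) if r["allowed_values"] != "" else None
            ),
            is_diagnosis=r["is_diagnosis"] == "1",
        )
        for r in _read_table(path, "variables")
    ]
    responses = [
        StagingResponse(
            individual_id=r["individual_id"],
            wave_id=r["wave_id"],
            variable_id=r["variable_id"],
            raw_value=r["raw_value"],
            numeric_value=_opt_float(r["numeric_value"]),
        )
        for r in _read_table(path, "responses")
    ]
    bundle = StagingBundle(
        study_id=study_id,
        households=households,
        individuals=individuals,
        waves=waves,
        variables=variables,
        responses=responses,
    )
    return bundle.validate_references()


def _write_table(path: Path, name: str, rows: list[list[str]]) -> Path:
    fp = path / f"{name}.csv"
    with open(fp, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(TABLE_COLUMNS[name])
        writer.writerows(rows)
    return fp


def write_staging(bundle: StagingBundle, path) -> dict[str, Path]:
    """Write the bundle as one CSV per table; returns a {table: path} manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {}
    manifest["households"] = _write_table(
        path,
        "households",
        [
            [h.household_id, h.location_label, _s(h.latitude), _s(h.longitude)]
            for h in bundle.households
        ],
    )
    manifest["individuals"] = _write_table(
        path,
        "individuals",
        [
            [
                i.individual_id,
                _s(i.household_id),
                _s(i.sex_code),
                _s(i.birth_date),
                _s(i.race_code),
                _s(i.ethnicity_code),
                _s(i.marital_status_code),
            ]
            for i in bundle.individuals
        ],
    )
    manifest["waves"] = _write_table(
        path,
        "waves",
        [[w.wave_id, w.study_id, _s(w.wave_index), _s(w.wave_date)] for w in bundle.waves],
    )
    manifest["variables"] = _write_table(
        path,
        "variables",
        [
            [
                v.variable_id,
                _s(v.instrument_id),
                v.value_kind,
                _s(v.unit_label),
                "|".join(v.allowed_values) if v.allowed_values is not None else "",
                _s(v.is_diagnosis),
            ]
            for v in bundle.variables
        ],
    )
    manifest["responses"] = _write_table(
        path,
        "responses",
        [
            [r.individual_id, r.wave_id, r.variable_id, r.raw_value, _s(r.numeric_value)]
            for r in bundle.responses
        ],
    )
    return manifest
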