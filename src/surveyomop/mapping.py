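"""Variable-to-concept mapping: domain routing, resolution, review queue.

The authoritative mapping source is a curated table (an explicit input file
produced by expert review), never an automatic matcher; a trivial
exact-name matcher exists as an opt-in convenience only.  Variables the
table cannot resolve are never dropped silently — they are routed to a
review queue with a reason (no standard equivalent, deprecated target, or
explicitly excluded as unmappable).

Domain routing follows OMOP conventions: quantitative variables with a
defined unit or scale go to Measurement; qualitative assessments, symptom
presence and questionnaire responses without intrinsic units go to
Observation; variables flagged as diagnoses go to Condition.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .instruments import STANDARD_INSTRUMENTS
from .staging import StagingBundle, StagingVariable
from .vocab import ConceptRegistry, mint_local_concept, pair_relationship

__all__ = [
    "MappingEntry",
    "ReviewQueueEntry",
    "MappingPlan",
    "MappingTable",
    "route_domain",
    "resolve_mapping",
    "compile_mapping_plan",
    "synthesize_mapping_table",
    "mint_score_concepts",
    "load_mapping_table",
    "write_mapping_table",
]

MAPPING_COLUMNS = [
    "variable_id",
    "target_concept_id",
    "target_domain",
    "value_label",
    "value_concept_id",
    "unit_concept_id",
]

REVIEW_REASONS = ("no_equivalent", "deprecated", "excluded_unmappable")


@dataclass(frozen=True)
class MappingEntry:
    variable_id: str
    target_concept_id: int
    target_domain: str  # Measurement | Observation | Condition
    value_map: dict[str, int] = field(default_factory=dict)
    unit_concept: Optional[int] = None

    def __hash__(self):
        return hash((self.variable_id, self.target_concept_id))


@dataclass(frozen=True)
class ReviewQueueEntry:
    variable_id: str
    reason: str


@dataclass
class MappingPlan:
    entries: dict[str, MappingEntry] = field(default_factory=dict)
    review_queue: list[ReviewQueueEntry] = field(default_factory=list)

    @property
    def coverage(self) -> float:
        """Mapped fraction of distinct variables; 1.0 for an empty plan."""
        unmapped = {e.variable_id for e in self.review_queue}
        total = len(self.entries) + len(unmapped)
        return 1.0 if total == 0 else len(self.entries) / total


@dataclass
class MappingTable:
    """Curated variable -> concept assignments (one row per value label)."""

    rows: list[dict] = field(default_factory=list)

    def for_variable(self, variable_id: str) -> list[dict]:
        return [r for r in self.rows if r["variable_id"] == variable_id]


def route_domain(variable: StagingVariable) -> str:
    """OMOP domain for a staging variable (total function)."""
    if variable.is_diagnosis:
        return "Condition"
    if variable.value_kind == "quantitative" and variable.unit_label is not None:
        return "Measurement"
    return "Observation"


def resolve_mapping(
    variable: StagingVariable,
    registry: ConceptRegistry,
    mapping_table: MappingTable,
    *,
    reference_date: Optional[dt.date] = None,
    auto_match: bool = False,
):
    """Resolve one variable to a :class:`MappingEntry` or a review entry.

    ``reference_date`` anchors the deprecation test (a target concept whose
    valid_end precedes it is deprecated); defaults to today only when not
    supplied.  ``auto_match`` enables the exact-name fallback matcher.
    """
    if reference_date is None:
        reference_date = dt.date.today()
    rows = mapping_table.for_variable(variable.variable_id)
    if not rows:
        if auto_match:
            for c in registry.concepts.values():
                if c.concept_name == variable.variable_id:
                    return MappingEntry(
                        variable_id=variable.variable_id,
                        target_concept_id=c.concept_id,
                        target_domain=route_domain(variable),
                    )
        return ReviewQueueEntry(variable.variable_id, "no_equivalent")

    head = rows[0]
    try:
        target_id = int(head["target_concept_id"])
    except (TypeError, ValueError):
        return ReviewQueueEntry(variable.variable_id, "excluded_unmappable")
    concept = registry.get(target_id)
    if concept is None:
        return ReviewQueueEntry(variable.variable_id, "no_equivalent")
    if concept.valid_end < reference_date:
        return ReviewQueueEntry(variable.variable_id, "deprecated")

    value_map: dict[str, int] = {}
    for r in rows:
        if not r.get("value_label"):
            continue
        vc = int(r["value_concept_id"])
        if vc not in registry:
            return ReviewQueueEntry(variable.variable_id, "no_equivalent")
        value_map[r["value_label"]] = vc
    unit = head.get("unit_concept_id") or None
    unit_id = int(unit) if unit else None
    if unit_id is not None and unit_id not in registry:
        return ReviewQueueEntry(variable.variable_id, "no_equivalent")
    domain = head.get("target_domain") or route_domain(variable)
    return MappingEntry(
        variable_id=variable.variable_id,
        target_concept_id=target_id,
        target_domain=domain,
        value_map=value_map,
        unit_concept=unit_id,
    )


def compile_mapping_plan(
    bundle: StagingBundle,
    registry: ConceptRegistry,
    mapping_table: MappingTable,
    *,
    reference_date: Optional[dt.date] = None,
    auto_match: bool = False,
) -> MappingPlan:
    """One mapping decision per distinct staging variable; deterministic."""
    plan = MappingPlan()
    seen: set[str] = set()
    for variable in bundle.variables:
        if variable.variable_id in seen:
            continue
        seen.add(variable.variable_id)
        decision = resolve_mapping(
            variable,
            registry,
            mapping_table,
            reference_date=reference_date,
            auto_match=auto_match,
        )
        if isinstance(decision, MappingEntry):
            plan.entries[variable.variable_id] = decision
        else:
            plan.review_queue.append(decision)
    return plan


# ---------------------------------------------------------------------------
# demo/synthetic support: mint local concepts covering a variable set

def synthesize_mapping_table(
    bundle: StagingBundle, registry: ConceptRegistry
) -> MappingTable:
    """Mint local concepts covering every variable in ``bundle`` and return
    the corresponding mapping table.

    Emulates the end state of a manual curation pass over a study whose
    terms have no standard equivalents: each variable gets an
    Observation/Measurement/Condition concept, each categorical response
    label a Meas Value answer concept linked with "Has answer".
    """
    table = MappingTable()
    for variable in {v.variable_id: v for v in bundle.variables}.values():
        domain = route_domain(variable)
        concept = mint_local_concept(registry, variable.variable_id, domain)
        if variable.allowed_values:
            for label in variable.allowed_values:
                answer = mint_local_concept(
                    registry, f"{variable.variable_id}={label}", "Meas Value"
                )
                pair_relationship(registry, concept.concept_id, answer.concept_id, "Has answer")
                table.rows.append(
                    {
                        "variable_id": variable.variable_id,
                        "target_concept_id": str(concept.concept_id),
                        "target_domain": domain,
                        "value_label": label,
                        "value_concept_id": str(answer.concept_id),
                        "unit_concept_id": "",
                    }
                )
        else:
            table.rows.append(
                {
                    "variable_id": variable.variable_id,
                    "target_concept_id": str(concept.concept_id),
                    "target_domain": domain,
                    "value_label": "",
                    "value_concept_id": "",
                    "unit_concept_id": "",
                }
            )
    return table


def mint_score_concepts(
    registry: ConceptRegistry, instruments: tuple[str, ...]
) -> dict[str, int]:
    """Local Measurement concepts for instrument composite scores."""
    out = {}
    for inst in instruments:
        if inst not in STANDARD_INSTRUMENTS:
            raise KeyError(f"unknown instrument {inst!r}")
        c = mint_local_concept(registry, f"{inst} total score", "Measurement")
        out[inst] = c.concept_id
    return out


def load_mapping_table(path) -> MappingTable:
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != MAPPING_COLUMNS:
            raise ValueError(f"{path}: malformed mapping table header {reader.fieldnames!r}")
        return MappingTable(rows=list(reader))


def write_mapping_table(table: MappingTable, path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=MAPPING_COLUMNS, lineterminator="\n")
        writer.writeheader()
        writer.writerows(table.rows)
    return path
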