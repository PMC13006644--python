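"""OMOP vocabulary tables with a local-concept extension.

Source terms without a standard OMOP equivalent are minted as *local*
concepts in a project vocabulary, with concept_ids above 2,000,000,000 so
they can never collide with standard concept ids.  Local concepts are
standard-flagged ('S') and used directly in ``*_concept_id`` fields so that
downstream cohort tools can see them; this deliberately departs from the
THEMIS recommendation of hiding custom codes in ``*_source_concept_id``.

Relationships are always stored as inverse pairs ("Maps to"/"Maps from",
"Has answer"/"Is an answer of"), mirroring how the OMOP
concept_relationship table is distributed.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

__all__ = [
    "Concept",
    "VocabularyEntry",
    "ConceptRelationship",
    "ConceptRegistry",
    "VocabError",
    "LOCAL_ID_FLOOR",
    "DEFAULT_LOCAL_VOCAB",
    "DOMAINS",
    "mint_local_concept",
    "pair_relationship",
    "classify_concepts",
    "build_fixture_vocabulary",
    "bootstrap_registry",
    "load_vocabulary",
    "write_vocabulary",
]

LOCAL_ID_FLOOR = 2_000_000_000
DEFAULT_LOCAL_VOCAB = "MHLOCAL"

DOMAINS = frozenset(
    {
        "Observation",
        "Meas Value",
        "Measurement",
        "Condition",
        "Geography",
        "Metadata",
        "Race",
        "Gender",
        "Condition Status",
        "Ethnicity",
        "Type Concept",
        "Visit",
    }
)

RELATIONSHIP_INVERSES = {
    "Maps to": "Maps from",
    "Maps from": "Maps to",
    "Has answer": "Is an answer of",
    "Is an answer of": "Has answer",
}

_DATE_MIN = dt.date(1970, 1, 1)
_DATE_MAX = dt.date(2099, 12, 31)


class VocabError(ValueError):
    pass


@dataclass(frozen=True)
class Concept:
    concept_id: int
    concept_name: str
    domain_id: str
    vocabulary_id: str
    concept_class_id: str = "Clinical Observation"
    standard_flag: str = "S"  # 'S' or '' (non-standard)
    concept_code: str = ""
    valid_start: dt.date = _DATE_MIN
    valid_end: dt.date = _DATE_MAX

    @property
    def is_deprecated(self) -> bool:
        return self.valid_end < dt.date.today()


@dataclass(frozen=True)
class VocabularyEntry:
    vocab_id: str
    vocab_name: str
    vocab_reference: str = ""
    vocab_version: str = "v1"
    vocab_concept_id: int = 0


@dataclass(frozen=True)
class ConceptRelationship:
    concept_id_1: int
    concept_id_2: int
    relationship_id: str


@dataclass
class ConceptRegistry:
    """Concept, vocabulary and relationship tables plus the local-id cursor."""

    local_vocab: str = DEFAULT_LOCAL_VOCAB
    concepts: dict[int, Concept] = field(default_factory=dict)
    vocabularies: dict[str, VocabularyEntry] = field(default_factory=dict)
    relationships: list[ConceptRelationship] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.local_vocab not in self.vocabularies:
            self.vocabularies[self.local_vocab] = VocabularyEntry(
                vocab_id=self.local_vocab,
                vocab_name="Local Custom Vocabulary",
                vocab_version="v1",
                vocab_concept_id=0,
            )

    # -- membership -----------------------------------------------------
    def __contains__(self, concept_id: int) -> bool:
        return concept_id in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def get(self, concept_id: int) -> Optional[Concept]:
        return self.concepts.get(concept_id)

    def is_local(self, concept: Concept) -> bool:
        return concept.vocabulary_id == self.local_vocab

    def add_concept(self, concept: Concept) -> None:
        if concept.domain_id not in DOMAINS:
            raise VocabError(f"unknown domain_id {concept.domain_id!r}")
        if concept.concept_id in self.concepts:
            raise VocabError(f"duplicate concept_id {concept.concept_id}")
        if self.is_local(concept) and concept.concept_id <= LOCAL_ID_FLOOR:
            raise VocabError(
                f"local concept_id {concept.concept_id} must exceed {LOCAL_ID_FLOOR}"
            )
        if not self.is_local(concept) and concept.concept_id > LOCAL_ID_FLOOR:
            raise VocabError(
                f"standard concept_id {concept.concept_id} inside the local id range"
            )
        self.concepts[concept.concept_id] = concept

    @property
    def next_local_id(self) -> int:
        local_ids = [
            c.concept_id for c in self.concepts.values() if self.is_local(c)
        ]
        return max([LOCAL_ID_FLOOR] + local_ids) + 1

    def concepts_in_domain(self, domain_id: str) -> list[Concept]:
        return [c for c in self.concepts.values() if c.domain_id == domain_id]

    def has_relationship(self, a: int, b: int, relationship_id: str) -> bool:
        return any(
            r.concept_id_1 == a and r.concept_id_2 == b and r.relationship_id == relationship_id
            for r in self.relationships
        )


def mint_local_concept(
    registry: ConceptRegistry,
    name: str,
    domain_id: str,
    *,
    concept_class_id: str = "Clinical Observation",
    concept_code: str = "",
) -> Concept:
    """Allocate the next 2-billion-range id for a local concept.

    Minting is idempotent on (name, domain): re-minting an existing pair
    returns the existing concept unchanged.  Local concepts carry the
    standard flag 'S' so they are directly usable in ``*_concept_id``
    fields and cohort definitions.
    """
    if domain_id not in DOMAINS:
        raise VocabError(f"unknown domain_id {domain_id!r}")
    for c in registry.concepts.values():
        if registry.is_local(c) and c.concept_name == name and c.domain_id == domain_id:
            return c
    concept = Concept(
        concept_id=registry.next_local_id,
        concept_name=name,
        domain_id=domain_id,
        vocabulary_id=registry.local_vocab,
        concept_class_id=concept_class_id,
        standard_flag="S",
        concept_code=concept_code or name,
    )
    registry.add_concept(concept)
    return concept


def pair_relationship(
    registry: ConceptRegistry, a: int, b: int, relationship_id: str
) -> tuple[ConceptRelationship, ConceptRelationship]:
    """Insert a relationship row and its inverse, exactly once each."""
    if relationship_id not in RELATIONSHIP_INVERSES:
        raise VocabError(f"unsupported relationship_id {relationship_id!r}")
    if a not in registry or b not in registry:
        raise VocabError(f"relationship endpoints must be registered concepts: {a}, {b}")
    inverse = RELATIONSHIP_INVERSES[relationship_id]
    fwd = ConceptRelationship(a, b, relationship_id)
    rev = ConceptRelationship(b, a, inverse)
    if not registry.has_relationship(a, b, relationship_id):
        registry.relationships.append(fwd)
    if not registry.has_relationship(b, a, inverse):
        registry.relationships.append(rev)
    return fwd, rev


def classify_concepts(registry: ConceptRegistry) -> dict[str, dict[str, int]]:
    """Per-domain standard/local concept counts.

    Returns ``{domain: {"standard": n, "local": n}}``; counts over all
    domains sum to the registry size.
    """
    out: dict[str, dict[str, int]] = {}
    for c in registry.concepts.values():
        bucket = out.setdefault(c.domain_id, {"standard": 0, "local": 0})
        bucket["local" if registry.is_local(c) else "standard"] += 1
    return out


# Composition of the harmonised concept inventory: 255 unique concepts, 227
# standard (89.0%) and 28 local (11.0%).  Local concepts concentrate in
# Observation (20), Meas Value (6) and Measurement (2); the standard side is
# dominated by Observation and Meas Value, with Condition fully standard and
# one concept each in Ethnicity, Condition Status, Type Concept and Visit.
FIXTURE_COMPOSITION = {
    "standard": {
        "Observation": 108,
        "Meas Value": 69,
        "Measurement": 9,
        "Condition": 25,
        "Ethnicity": 1,
        "Condition Status": 1,
        "Type Concept": 1,
        "Visit": 1,
        "Gender": 2,
        "Race": 5,
        "Geography": 3,
        "Metadata": 2,
    },
    "local": {
        "Observation": 20,
        "Meas Value": 6,
        "Measurement": 2,
    },
}


def build_fixture_vocabulary(local_vocab: str = DEFAULT_LOCAL_VOCAB) -> ConceptRegistry:
    """Synthetic 255-concept registry reproducing the harmonised-domain
    composition above.

    Concept ids and names are synthetic stand-ins (the real inventory is not
    redistributable); only the per-domain standard/local counts are
    meaningful.
    """
    registry = ConceptRegistry(local_vocab=local_vocab)
    registry.vocabularies.setdefault(
        "SYNTH-STD", VocabularyEntry("SYNTH-STD", "Synthetic standard vocabulary stand-in")
    )
    next_std = 44_800_001
    for domain, n in FIXTURE_COMPOSITION["standard"].items():
        for k in range(n):
            registry.add_concept(
                Concept(
                    concept_id=next_std,
                    concept_name=f"{domain} standard concept {k + 1}",
                    domain_id=domain,
                    vocabulary_id="SYNTH-STD",
                    standard_flag="S",
                )
            )
            next_std += 1
    for domain, n in FIXTURE_COMPOSITION["local"].items():
        for k in range(n):
            mint_local_concept(registry, f"{domain} local concept {k + 1}", domain)
    return registry


# Canonical OMOP concept ids used for demographics and provenance typing.
STANDARD_SEED_CONCEPTS = [
    Concept(8507, "MALE", "Gender", "Gender", "Gender"),
    Concept(8532, "FEMALE", "Gender", "Gender", "Gender"),
    Concept(8516, "Black or African American", "Race", "Race", "Race"),
    Concept(8527, "White", "Race", "Race", "Race"),
    Concept(8522, "Other Race", "Race", "Race", "Race"),
    Concept(38003564, "Not Hispanic or Latino", "Ethnicity", "Ethnicity", "Ethnicity"),
    Concept(38003563, "Hispanic or Latino", "Ethnicity", "Ethnicity", "Ethnicity"),
    Concept(32862, "Patient filled survey", "Type Concept", "Type Concept", "Type Concept"),
    Concept(581477, "Home Visit", "Visit", "Visit", "Visit"),
]


def bootstrap_registry(local_vocab: str = DEFAULT_LOCAL_VOCAB) -> ConceptRegistry:
    """Registry preloaded with the standard demographic/provenance concepts
    the ETL defaults reference (genders, races, ethnicities, survey type
    concept, home-visit concept)."""
    registry = ConceptRegistry(local_vocab=local_vocab)
    for vocab_id in ("Gender", "Race", "Ethnicity", "Type Concept", "Visit"):
        registry.vocabularies.setdefault(
            vocab_id, VocabularyEntry(vocab_id, f"OMOP {vocab_id}")
        )
    for c in STANDARD_SEED_CONCEPTS:
        registry.add_concept(c)
    return registry


# ---------------------------------------------------------------------------
# Athena-style I/O: tab-separated, header row, no quoting, dates YYYYMMDD

_CONCEPT_COLS = [
    "concept_id",
    "concept_name",
    "domain_id",
    "vocabulary_id",
    "concept_class_id",
    "standard_concept",
    "concept_code",
    "valid_start_date",
    "valid_end_date",
    "invalid_reason",
]
_VOCAB_COLS = [
    "vocabulary_id",
    "vocabulary_name",
    "vocabulary_reference",
    "vocabulary_version",
    "vocabulary_concept_id",
]
_REL_COLS = [
    "concept_id_1",
    "concept_id_2",
    "relationship_id",
    "valid_start_date",
    "valid_end_date",
    "invalid_reason",
]


def _athena_date(d: dt.date) -> str:
    return d.strftime("%Y%m%d")


def _parse_athena_date(text: str) -> dt.date:
    return dt.datetime.strptime(text, "%Y%m%d").date()


def _write_tsv(path: Path, columns: list[str], rows: list[list[str]]) -> Path:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE, lineterminator="\n")
        writer.writerow(columns)
        writer.writerows(rows)
    return path


def write_vocabulary(registry: ConceptRegistry, path) -> dict[str, Path]:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {}
    manifest["CONCEPT"] = _write_tsv(
        path / "CONCEPT.csv",
        _CONCEPT_COLS,
        [
            [
                str(c.concept_id),
                c.concept_name,
                c.domain_id,
                c.vocabulary_id,
                c.concept_class_id,
                c.standard_flag if c.standard_flag == "S" else "",
                c.concept_code,
                _athena_date(c.valid_start),
                _athena_date(c.valid_end),
                "",
            ]
            for c in sorted(registry.concepts.values(), key=lambda c: c.concept_id)
        ],
    )
    manifest["VOCABULARY"] = _write_tsv(
        path / "VOCABULARY.csv",
        _VOCAB_COLS,
        [
            [v.vocab_id, v.vocab_name, v.vocab_reference, v.vocab_version, str(v.vocab_concept_id)]
            for v in sorted(registry.vocabularies.values(), key=lambda v: v.vocab_id)
        ],
    )
    manifest["CONCEPT_RELATIONSHIP"] = _write_tsv(
        path / "CONCEPT_RELATIONSHIP.csv",
        _REL_COLS,
        [
            [
                str(r.concept_id_1),
                str(r.concept_id_2),
                r.relationship_id,
                _athena_date(_DATE_MIN),
                _athena_date(_DATE_MAX),
                "",
            ]
            for r in registry.relationships
        ],
    )
    return manifest


def _read_tsv(path: Path, columns: list[str]) -> list[dict]:
    if not path.exists():
        raise VocabError(f"missing vocabulary file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        header = next(reader, None)
        if header != columns:
            raise VocabError(f"{path}: malformed header {header!r}")
        return [dict(zip(columns, row)) for row in reader]


def load_vocabulary(path, local_vocab: str = DEFAULT_LOCAL_VOCAB) -> ConceptRegistry:
    """Load CONCEPT / VOCABULARY / CONCEPT_RELATIONSHIP tables.

    A duplicate concept_id is fatal and the error names the id.
    """
    path = Path(path)
    registry = ConceptRegistry(local_vocab=local_vocab)
    registry.vocabularies.clear()
    for r in _read_tsv(path / "VOCABULARY.csv", _VOCAB_COLS):
        entry = VocabularyEntry(
            vocab_id=r["vocabulary_id"],
            vocab_name=r["vocabulary_name"],
            vocab_reference=r["vocabulary_reference"],
            vocab_version=r["vocabulary_version"],
            vocab_concept_id=int(r["vocabulary_concept_id"]),
        )
        if entry.vocab_id in registry.vocabularies:
            raise VocabError(f"duplicate vocabulary_id {entry.vocab_id!r}")
        registry.vocabularies[entry.vocab_id] = entry
    registry.vocabularies.setdefault(
        local_vocab, VocabularyEntry(local_vocab, "Local Custom Vocabulary")
    )
    seen: set[int] = set()
    for r in _read_tsv(path / "CONCEPT.csv", _CONCEPT_COLS):
        cid = int(r["concept_id"])
        if cid in seen:
            raise VocabError(f"duplicate concept_id {cid} in CONCEPT table")
        seen.add(cid)
        registry.add_concept(
            Concept(
                concept_id=cid,
                concept_name=r["concept_name"],
                domain_id=r["domain_id"],
                vocabulary_id=r["vocabulary_id"],
                concept_class_id=r["concept_class_id"],
                standard_flag="S" if r["standard_concept"] == "S" else "",
                concept_code=r["concept_code"],
                valid_start=_parse_athena_date(r["valid_start_date"]),
                valid_end=_parse_athena_date(r["valid_end_date"]),
            )
        )
    for r in _read_tsv(path / "CONCEPT_RELATIONSHIP.csv", _REL_COLS):
        registry.relationships.append(
            ConceptRelationship(
                concept_id_1=int(r["concept_id_1"]),
                concept_id_2=int(r["concept_id_2"]),
                relationship_id=r["relationship_id"],
            )
        )
    return registry
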