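"""Vocabulary registry: local-id discipline, paired relationships, the
composition fixture, and Athena-dialect round trips."""

import pytest

from surveyomop.vocab import (
    Concept,
    ConceptRegistry,
    VocabError,
    build_fixture_vocabulary,
    bootstrap_registry,
    classify_concepts,
    load_vocabulary,
    mint_local_concept,
    pair_relationship,
    write_vocabulary,
)


class TestMinting:
    def test_first_minted_id_is_two_billion_plus_one(self):
        registry = ConceptRegistry()
        c = mint_local_concept(registry, "local term", "Observation")
        assert c.concept_id == 2_000_000_001

    def test_sequential_allocation(self):
        registry = ConceptRegistry()
        for k in range(3):
            mint_local_concept(registry, f"t{k}", "Observation")
        assert registry.next_local_id == 2_000_000_004

    def test_disjoint_from_preloaded_standard_ids(self):
        registry = bootstrap_registry()
        registry.add_concept(
            Concept(45_000_000, "std", "Observation", "SYNTH-STD")
        )
        c = mint_local_concept(registry, "local", "Observation")
        assert c.concept_id > 2_000_000_000

    def test_minting_is_idempotent_on_name_and_domain(self):
        registry = ConceptRegistry()
        a = mint_local_concept(registry, "term", "Observation")
        b = mint_local_concept(registry, "term", "Observation")
        assert a == b and len(registry) == 1

    def test_local_concepts_are_standard_flagged(self):
        registry = ConceptRegistry()
        assert mint_local_concept(registry, "t", "Meas Value").standard_flag == "S"

    def test_unknown_domain_is_fatal(self):
        with pytest.raises(VocabError, match="domain"):
            mint_local_concept(ConceptRegistry(), "t", "Bogus Domain")


class TestRelationships:
    def test_maps_to_creates_inverse_maps_from(self):
        registry = ConceptRegistry()
        a = mint_local_concept(registry, "a", "Observation")
        b = mint_local_concept(registry, "b", "Observation")
        pair_relationship(registry, a.concept_id, b.concept_id, "Maps to")
        assert registry.has_relationship(a.concept_id, b.concept_id, "Maps to")
        assert registry.has_relationship(b.concept_id, a.concept_id, "Maps from")

    def test_has_answer_creates_is_an_answer_of(self):
        registry = ConceptRegistry()
        q = mint_local_concept(registry, "q", "Observation")
        ans = mint_local_concept(registry, "ans", "Meas Value")
        pair_relationship(registry, q.concept_id, ans.concept_id, "Has answer")
        assert registry.has_relationship(ans.concept_id, q.concept_id, "Is an answer of")

    def test_repeat_call_is_idempotent(self):
        registry = ConceptRegistry()
        a = mint_local_concept(registry, "a", "Observation")
        b = mint_local_concept(registry, "b", "Observation")
        for _ in range(3):
            pair_relationship(registry, a.concept_id, b.concept_id, "Maps to")
        assert len(registry.relationships) == 2

    def test_unknown_relationship_is_fatal(self):
        registry = ConceptRegistry()
        a = mint_local_concept(registry, "a", "Observation")
        with pytest.raises(VocabError, match="relationship"):
            pair_relationship(registry, a.concept_id, a.concept_id, "Subsumes")

    def test_every_relationship_row_has_its_inverse(self):
        registry = build_fixture_vocabulary()
        ids = list(registry.concepts)
        pair_relationship(registry, ids[0], ids[1], "Maps to")
        pair_relationship(registry, ids[2], ids[3], "Has answer")
        inverses = {
            "Maps to": "Maps from",
            "Maps from": "Maps to",
            "Has answer": "Is an answer of",
            "Is an answer of": "Has answer",
        }
        for r in registry.relationships:
            assert registry.has_relationship(
                r.concept_id_2, r.concept_id_1, inverses[r.relationship_id]
            )


class TestFixtureComposition:
    def test_total_is_255(self):
        assert len(build_fixture_vocabulary()) == 255

    def test_standard_local_split_227_28(self):
        counts = classify_concepts(build_fixture_vocabulary())
        assert sum(v["standard"] for v in counts.values()) == 227
        assert sum(v["local"] for v in counts.values()) == 28

    def test_local_concepts_per_domain(self):
        counts = classify_concepts(build_fixture_vocabulary())
        locals_ = {d: v["local"] for d, v in counts.items() if v["local"]}
        assert locals_ == {"Observation": 20, "Meas Value": 6, "Measurement": 2}

    def test_all_local_concepts_standard_flagged(self):
        registry = build_fixture_vocabulary()
        local = [c for c in registry.concepts.values() if registry.is_local(c)]
        assert len(local) == 28
        assert all(c.standard_flag == "S" for c in local)

    def test_counts_conserve_registry_size(self):
        registry = build_fixture_vocabulary()
        counts = classify_concepts(registry)
        assert sum(v["standard"] + v["local"] for v in counts.values()) == len(registry)

    def test_single_concept_domains(self):
        counts = classify_concepts(build_fixture_vocabulary())
        for domain in ("Ethnicity", "Condition Status", "Type Concept", "Visit"):
            assert counts[domain] == {"standard": 1, "local": 0}


class TestRoundTrip:
    def test_fixture_round_trips(self, tmp_path):
        registry = build_fixture_vocabulary()
        ids = list(registry.concepts)
        pair_relationship(registry, ids[0], ids[1], "Maps to")
        write_vocabulary(registry, tmp_path)
        loaded = load_vocabulary(tmp_path)
        assert loaded.concepts == registry.concepts
        assert loaded.vocabularies == registry.vocabularies
        assert set(loaded.relationships) == set(registry.relationships)

    def test_duplicate_concept_id_is_fatal_naming_the_id(self, tmp_path):
        registry = bootstrap_registry()
        write_vocabulary(registry, tmp_path)
        fp = tmp_path / "CONCEPT.csv"
        lines = fp.read_text(encoding="utf-8").splitlines()
        fp.write_text("\n".join(lines + [lines[1]]) + "\n", encoding="utf-8")
        with pytest.raises(VocabError, match="8507"):
            load_vocabulary(tmp_path)

    def test_empty_concept_file_gives_empty_registry(self, tmp_path):
        write_vocabulary(ConceptRegistry(), tmp_path)
        assert len(load_vocabulary(tmp_path)) == 0
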