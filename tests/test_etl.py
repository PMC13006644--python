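"""ETL: table counts, exclude-or-null-and-log cleaning, audit conservation,
referential closure, round trips, determinism."""

import datetime as dt

import pytest

from surveyomop.etl import (
    ConditionRule,
    EtlConfig,
    EtlError,
    load_cdm,
    run_etl,
    write_cdm,
)
from surveyomop.mapping import MappingPlan, compile_mapping_plan, synthesize_mapping_table
from surveyomop.staging import StagingBundle, StagingIndividual
from surveyomop.synth import ErrorInjectionSpec, StudyConfig, generate_study, inject_errors
from surveyomop.vocab import bootstrap_registry

from conftest import build_pipeline

GAD7_CONFIG = StudyConfig(
    n_individuals=10,
    n_waves=2,
    instruments=("GAD-7",),
    covariates=(),
    item_missingness=0.0,
    seed=1,
)


def test_counting_under_default_routing():
    # 10 persons x 2 waves, GAD-7 only: 20 visits, 20 composite-score
    # measurements, 10*2*7 = 140 item observations
    _b, _r, _p, _c, cdm = build_pipeline(GAD7_CONFIG)
    assert len(cdm.person) == 10
    assert len(cdm.visit_occurrence) == 20
    assert len(cdm.measurement) == 20
    assert len(cdm.observation) == 140
    assert len(cdm.error_log) == 0


def test_null_identifier_is_excluded_and_logged():
    bundle = generate_study(GAD7_CONFIG)
    victim = bundle.individuals[3]
    bundle.individuals[3] = StagingIndividual(
        "", victim.household_id, victim.sex_code, victim.birth_date
    )
    _b, _r, _p, _c, cdm = build_pipeline(GAD7_CONFIG, bundle=bundle)
    assert len(cdm.person) == 9
    hits = cdm.error_log[cdm.error_log.rule == "null_person_id"]
    assert len(hits) == 1 and hits.action.iloc[0] == "excluded"


def test_future_birth_date_is_nulled_then_person_excluded():
    bundle = generate_study(GAD7_CONFIG)
    victim = bundle.individuals[0]
    bundle.individuals[0] = StagingIndividual(
        victim.individual_id, victim.household_id, victim.sex_code, dt.date(2050, 1, 1)
    )
    _b, _r, _p, _c, cdm = build_pipeline(GAD7_CONFIG, bundle=bundle)
    nulled = cdm.error_log[cdm.error_log.rule == "future_birth_date"]
    assert len(nulled) == 1 and nulled.action.iloc[0] == "nulled"
    assert len(cdm.person) == 9  # no placeholder birth year is invented


def test_event_before_birth_dates_are_nulled_and_logged():
    bundle = generate_study(GAD7_CONFIG)
    spec = ErrorInjectionSpec(event_before_birth=1, seed=4)
    corrupted, ledger = inject_errors(bundle, spec)
    _b, _r, _p, _c, cdm = build_pipeline(GAD7_CONFIG, bundle=corrupted)
    hits = cdm.error_log[cdm.error_log.rule == "event_before_birth"]
    assert set(hits.action) == {"nulled"}
    persons = {k.split("|")[0] for k in hits.row_key}
    assert persons == ledger.keys("event_before_birth")
    # the nulled rows survive (nulled, not excluded)
    assert len(cdm.person) == 10


def test_consistent_rows_produce_no_log_entries(clean_study):
    assert len(clean_study["cdm"].error_log) == 0


def test_demographic_defaults():
    bundle = generate_study(GAD7_CONFIG)
    a, b = bundle.individuals[0], bundle.individuals[1]
    bundle.individuals[0] = StagingIndividual(a.individual_id, a.household_id, None, a.birth_date)
    bundle.individuals[1] = StagingIndividual(b.individual_id, b.household_id, "ZZ", b.birth_date)
    _b, _r, _p, _c, cdm = build_pipeline(GAD7_CONFIG, bundle=bundle)
    person = cdm.person.set_index("person_source_value")
    assert person.loc[a.individual_id, "gender_concept_id"] == 0  # absent -> unknown, silent
    assert person.loc[b.individual_id, "gender_concept_id"] == 0  # unmapped -> logged
    mapped = person.drop([a.individual_id, b.individual_id])
    assert set(mapped.gender_concept_id) <= {8507, 8532}
    log = cdm.error_log
    assert len(log[log.rule == "unmapped_demographic_code"]) == 1


def test_empty_bundle_yields_empty_tables_with_summary_rows():
    registry = bootstrap_registry()
    cdm = run_etl(StagingBundle(study_id="e"), MappingPlan(), registry, EtlConfig())
    for name, df in cdm.event_tables().items():
        assert len(df) == 0
    assert len(cdm.person) == 0
    summary = cdm.execution_summary
    assert len(summary) > 0
    assert set(summary.rows_in) == {0}


def test_unresolved_plan_reference_is_fatal():
    bundle = generate_study(GAD7_CONFIG)
    registry = bootstrap_registry()
    table = synthesize_mapping_table(bundle, registry)
    plan = compile_mapping_plan(bundle, registry, table, reference_date=dt.date(2024, 1, 1))
    bad = bootstrap_registry()  # lacks the minted concepts
    with pytest.raises(EtlError, match="unknown concept"):
        run_etl(bundle, plan, bad, EtlConfig())


def test_condition_rules_emit_condition_rows():
    bundle = generate_study(GAD7_CONFIG)
    registry = bootstrap_registry()
    table = synthesize_mapping_table(bundle, registry)
    from surveyomop.mapping import mint_score_concepts
    from surveyomop.vocab import mint_local_concept

    scores = mint_score_concepts(registry, ("GAD-7",))
    cond = mint_local_concept(registry, "Anxiety screening positive", "Condition")
    plan = compile_mapping_plan(bundle, registry, table, reference_date=dt.date(2024, 1, 1))
    config = EtlConfig(
        score_concepts=tuple(scores.items()),
        condition_rules=(ConditionRule("GAD-7", 5, cond.concept_id),),
    )
    cdm = run_etl(bundle, plan, registry, config)
    scores_df = cdm.measurement
    expected = int((scores_df.value_as_number >= 5).sum())
    assert len(cdm.condition_occurrence) == expected > 0
    assert set(cdm.condition_occurrence.condition_concept_id) == {cond.concept_id}


class TestAuditConservation:
    def test_rows_in_equals_out_plus_excluded_everywhere(self):
        config = StudyConfig(n_individuals=40, n_waves=3, seed=6)
        bundle, _ = inject_errors(
            generate_study(config),
            ErrorInjectionSpec(
                future_birth_dates=2, event_before_birth=2, null_required_ids=2,
                unmapped_codes=2, out_of_range_items=2, seed=6,
            ),
        )
        _b, _r, _p, _c, cdm = build_pipeline(config, bundle=bundle)
        for row in cdm.execution_summary.itertuples(index=False):
            assert row.rows_in == row.rows_out + row.rows_excluded

    def test_excluded_counts_match_error_log_per_step(self):
        config = StudyConfig(n_individuals=40, n_waves=3, seed=6)
        bundle, _ = inject_errors(
            generate_study(config),
            ErrorInjectionSpec(null_required_ids=3, future_birth_dates=2, seed=7),
        )
        _b, _r, _p, _c, cdm = build_pipeline(config, bundle=bundle)
        log = cdm.error_log
        excluded = log[log.action == "excluded"].groupby("step").size()
        for row in cdm.execution_summary.itertuples(index=False):
            assert row.rows_excluded == int(excluded.get(row.step, 0))


def test_referential_closure(clean_study):
    cdm = clean_study["cdm"]
    persons = set(cdm.person.person_id)
    visits = set(cdm.visit_occurrence.visit_occurrence_id)
    for name, df in cdm.event_tables().items():
        assert set(df.person_id) <= persons
        if name != "visit_occurrence":
            assert {v for v in df.visit_occurrence_id if v is not None} <= visits


def test_cdm_round_trip(tmp_path, clean_study):
    cdm = clean_study["cdm"]
    write_cdm(cdm, tmp_path)
    loaded = load_cdm(tmp_path)
    for name, df in cdm.tables().items():
        assert loaded.tables()[name].equals(df), name


def test_rerun_is_byte_identical(tmp_path):
    config = StudyConfig(n_individuals=15, n_waves=2, seed=8)
    for sub in ("a", "b"):
        _b, _r, _p, _c, cdm = build_pipeline(config)
        write_cdm(cdm, tmp_path / sub)
    for fp in sorted((tmp_path / "a").glob("*.csv")):
        assert fp.read_bytes() == (tmp_path / "b" / fp.name).read_bytes()
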