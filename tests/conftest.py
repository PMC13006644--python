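import pytest

from surveyomop.etl import EtlConfig, run_etl
from surveyomop.mapping import (
    compile_mapping_plan,
    mint_score_concepts,
    synthesize_mapping_table,
)
from surveyomop.synth import StudyConfig, generate_study
from surveyomop.vocab import bootstrap_registry


def build_pipeline(config: StudyConfig, bundle=None, condition_rules=()):
    """Run staging -> plan -> CDM for a bundle; returns all intermediates."""
    if bundle is None:
        bundle = generate_study(config)
    registry = bootstrap_registry()
    table = synthesize_mapping_table(bundle, registry)
    score_concepts = mint_score_concepts(registry, config.instruments)
    plan = compile_mapping_plan(
        bundle, registry, table, reference_date=config.reference_date
    )
    etl_config = EtlConfig(
        reference_date=config.reference_date,
        score_concepts=tuple(sorted(score_concepts.items())),
        condition_rules=tuple(condition_rules),
    )
    cdm = run_etl(bundle, plan, registry, etl_config)
    return bundle, registry, plan, etl_config, cdm


@pytest.fixture(scope="session")
def clean_study():
    """A clean (no injected errors) 50-person two-instrument study, ETL'd."""
    config = StudyConfig(
        study_id="clean",
        n_households=20,
        n_individuals=50,
        n_waves=3,
        instruments=("PHQ-9", "GAD-7"),
        item_missingness=0.02,
        demographic_missingness=0.05,
        seed=42,
    )
    bundle, registry, plan, etl_config, cdm = build_pipeline(config)
    return {
        "config": config,
        "bundle": bundle,
        "registry": registry,
        "plan": plan,
        "etl_config": etl_config,
        "cdm": cdm,
    }
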