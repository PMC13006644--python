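"""Quality-check engine: suite coverage, detection, rollups, invariants."""

import datetime as dt

import pytest

from surveyomop.quality import (
    CheckDefinition,
    CheckResult,
    QualityReport,
    default_check_suite,
    quality_config_for,
    run_checks,
    summarize_report,
)
from surveyomop.synth import ErrorInjectionSpec, StudyConfig, generate_study, inject_errors

from conftest import build_pipeline


def qconfig_for(study):
    return quality_config_for(study["plan"], study["bundle"], study["etl_config"])


class TestSuiteConstruction:
    def test_suite_has_at_least_thirty_checks(self):
        assert len(default_check_suite()) >= 30

    def test_every_cdm_table_has_a_completeness_check(self):
        suite = default_check_suite()
        covered = {c.table for c in suite if c.category == "Completeness"}
        assert covered >= {
            "location", "person", "visit_occurrence",
            "measurement", "observation", "condition_occurrence",
        }

    def test_concept_domain_checks_cover_event_tables(self):
        suite = default_check_suite()
        covered = {c.table for c in suite if c.predicate == "concept_domain"}
        assert covered >= {"measurement", "observation", "condition_occurrence"}

    def test_unknown_table_in_suite_is_fatal_before_execution(self, clean_study):
        bad = [CheckDefinition("x", "Completeness", "Verification", "nope", "f", "not_null")]
        with pytest.raises(ValueError, match="unknown table"):
            run_checks(clean_study["cdm"], clean_study["registry"], bad)


class TestExecution:
    def test_clean_bundle_passes_completeness_and_plausibility_fully(self, clean_study):
        config = qconfig_for(clean_study)
        report = run_checks(
            clean_study["cdm"], clean_study["registry"], default_check_suite(config), config
        )
        assert report.pass_rate("Completeness") == 1.0
        assert report.pass_rate("Plausibility") == 1.0

    def test_injected_out_of_range_items_are_detected_exactly(self):
        config = StudyConfig(n_individuals=30, n_waves=2, seed=13)
        bundle, ledger = inject_errors(
            generate_study(config), ErrorInjectionSpec(out_of_range_items=3, seed=13)
        )
        b, registry, plan, etl_config, cdm = build_pipeline(config, bundle=bundle)
        qconfig = quality_config_for(plan, b, etl_config)
        report = run_checks(cdm, registry, default_check_suite(qconfig), qconfig)
        range_viols = sum(
            r.rows_violating for r in report.results if r.check_id.startswith("plausibility_range_")
        )
        assert range_viols == ledger.count("out_of_range_items") == 3
        assert any(
            r.status == "FAIL" and r.check_id.startswith("plausibility_range_")
            for r in report.results
        )

    def test_empty_table_checks_are_not_applicable(self, clean_study):
        # the clean pipeline emits no condition rows (no condition rules)
        report = run_checks(
            clean_study["cdm"], clean_study["registry"], default_check_suite()
        )
        cond = [r for r in report.results if "condition_occurrence" in r.check_id]
        assert cond and all(r.status == "NOT_APPLICABLE" for r in cond)

    def test_determinism(self, clean_study):
        config = qconfig_for(clean_study)
        suite = default_check_suite(config)
        r1 = run_checks(clean_study["cdm"], clean_study["registry"], suite, config)
        r2 = run_checks(clean_study["cdm"], clean_study["registry"], suite, config)
        assert r1.results == r2.results

    def test_adding_a_violating_row_never_decreases_violations(self, clean_study):
        import copy

        config = qconfig_for(clean_study)
        suite = default_check_suite(config)
        base = run_checks(clean_study["cdm"], clean_study["registry"], suite, config)
        cdm = copy.deepcopy(clean_study["cdm"])
        row = dict(zip(cdm.measurement.columns, cdm.measurement.iloc[0]))
        row["measurement_id"] = 10**6
        row["value_as_number"] = 1e9  # violates the score range
        row["measurement_date"] = dt.date(1800, 1, 1)  # precedes any birth
        cdm.measurement.loc[len(cdm.measurement)] = row
        bumped = run_checks(cdm, clean_study["registry"], suite, config)
        for before, after in zip(base.results, bumped.results):
            assert after.rows_violating >= before.rows_violating


class TestRollup:
    def test_zero_fail_report_rolls_up_to_all_100(self, clean_study):
        config = qconfig_for(clean_study)
        report = run_checks(
            clean_study["cdm"], clean_study["registry"], default_check_suite(config), config
        )
        summary = summarize_report(report)
        assert all(
            pct in ("100%", "")
            for pct in summary[
                ["verification_pct_pass", "validation_pct_pass", "total_pct_pass"]
            ].values.flatten()
        )

    def test_verification_percentage_rounds_to_whole_percent(self):
        # 27 failures among 1861 verification checks round to a 99% pass rate
        results = [
            CheckResult(f"c{i}", "Plausibility", "Verification", 10, 0, "PASS")
            for i in range(1834)
        ] + [
            CheckResult(f"f{i}", "Plausibility", "Verification", 10, 1, "FAIL")
            for i in range(27)
        ]
        summary = summarize_report(QualityReport(results=results))
        total_row = summary[summary.category == "Total"].iloc[0]
        assert total_row.verification_pass == 1834
        assert total_row.verification_fail == 27
        assert total_row.verification_total == 1861
        assert total_row.verification_pct_pass == "99%"

    def test_empty_report_renders_blank_percentages(self):
        summary = summarize_report(QualityReport())
        assert set(summary.total_total) == {0}
        assert set(summary.total_pct_pass) == {""}
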