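"""Phase orchestration for the command-line pipeline.

Each phase reads its prerequisite artifacts from the working directory,
writes its own artifact directory, and updates a reproducibility manifest
(tool version, config digest, input/output file digests, seeds, per-phase
row counts).  The manifest timestamp comes from the config's injected clock,
never the wall clock, so two runs with identical inputs produce
byte-identical outputs including the manifest.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .analytics import (
    CohortDefinition,
    TimeAtRiskWindow,
    build_cohort,
    characterize_cohort,
    incidence_rates,
    pathway_sequences,
)
from .etl import ConditionRule, EtlConfig, load_cdm, run_etl, write_cdm
from .mapping import (
    compile_mapping_plan,
    load_mapping_table,
    mint_score_concepts,
    synthesize_mapping_table,
    write_mapping_table,
)
from .quality import default_check_suite, quality_config_for, run_checks, summarize_report
from .staging import load_staging, write_staging
from .synth import ErrorInjectionSpec, StudyConfig, generate_study, inject_errors
from .vocab import bootstrap_registry, load_vocabulary, mint_local_concept, write_vocabulary

__all__ = ["RunConfig", "MissingPhaseError", "PHASES", "run_phase", "DEFAULT_CONFIG"]

PHASES = ("synth", "vocab-build", "map", "etl-run", "qc-run", "cohort", "report")

DEFAULT_CONFIG: dict = {
    "workdir": "surveyomop_run",
    "clock": "2024-01-01T00:00:00",
    "study": {},  # StudyConfig field overrides
    "injection": None,  # ErrorInjectionSpec field overrides, or None
    "etl": {
        "condition_rules": [
            {"instrument": "PHQ-9", "min_score": 10, "concept_name": "Depression screening positive"},
            {"instrument": "GAD-7", "min_score": 10, "concept_name": "Anxiety screening positive"},
        ]
    },
    "cohorts": [
        {
            "cohort_id": "depression_disorder",
            "domain": "condition_occurrence",
            "concept_names": ["Depression screening positive"],
        },
        {
            "cohort_id": "anxiety_disorder",
            "domain": "condition_occurrence",
            "concept_names": ["Anxiety screening positive"],
        },
    ],
    "incidence": {
        "targets": ["depression_disorder"],
        "outcome": "anxiety_disorder",
        "start_offset_days": 0,
        "end_offset_days": 730,
    },
}


class MissingPhaseError(RuntimeError):
    def __init__(self, missing_phase: str, needed_by: str):
        self.missing_phase = missing_phase
        super().__init__(
            f"phase '{needed_by}' requires the artifact of phase '{missing_phase}'; "
            f"run '{missing_phase}' first"
        )


class RunConfig:
    """Top-level config: per-phase sections merged over packaged defaults."""

    def __init__(self, raw: Optional[dict] = None):
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        for key, value in (raw or {}).items():
            merged[key] = value
        self.raw = merged
        self.workdir = Path(merged["workdir"])
        self.clock = merged["clock"]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh) or {})

    # -- derived configs --------------------------------------------------
    def study_config(self) -> StudyConfig:
        kw = dict(self.raw.get("study") or {})
        for key in ("first_wave_date", "reference_date"):
            if key in kw and isinstance(kw[key], str):
                kw[key] = dt.date.fromisoformat(kw[key])
        for key in ("instruments", "covariates"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return StudyConfig(**kw)

    def injection_spec(self) -> Optional[ErrorInjectionSpec]:
        inj = self.raw.get("injection")
        if not inj:
            return None
        kw = dict(inj)
        if "reference_date" in kw and isinstance(kw["reference_date"], str):
            kw["reference_date"] = dt.date.fromisoformat(kw["reference_date"])
        return ErrorInjectionSpec(**kw)

    # -- paths -------------------------------------------------------------
    @property
    def staging_dir(self) -> Path:
        return self.workdir / "staging"

    @property
    def vocab_dir(self) -> Path:
        return self.workdir / "vocab"

    @property
    def mapping_dir(self) -> Path:
        return self.workdir / "mapping"

    @property
    def cdm_dir(self) -> Path:
        return self.workdir / "cdm"

    @property
    def qc_dir(self) -> Path:
        return self.workdir / "qc"

    @property
    def analytics_dir(self) -> Path:
        return self.workdir / "analytics"

    @property
    def manifest_path(self) -> Path:
        return self.workdir / "manifest.json"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _digest_dir(path: Path) -> dict[str, str]:
    return {p.name: _digest(p) for p in sorted(path.glob("*")) if p.is_file()}


def _update_manifest(cfg: RunConfig, phase: str, outputs: dict, row_counts: dict) -> None:
    manifest = {}
    if cfg.manifest_path.exists():
        manifest = json.loads(cfg.manifest_path.read_text(encoding="utf-8"))
    manifest.setdefault("tool_version", __version__)
    # digest the run *content*, not its location: the workdir path is excluded
    digestable = {k: v for k, v in cfg.raw.items() if k != "workdir"}
    manifest["config_digest"] = hashlib.sha256(
        json.dumps(digestable, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest["timestamp"] = cfg.clock
    seeds = manifest.setdefault("seeds", {})
    seeds["study"] = cfg.study_config().seed
    inj = cfg.injection_spec()
    if inj is not None:
        seeds["injection"] = inj.seed
    phases = manifest.setdefault("phases", {})
    phases[phase] = {"outputs": outputs, "row_counts": row_counts}
    cfg.manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def _require(cfg: RunConfig, directory: Path, phase: str, needed_by: str) -> None:
    if not directory.exists():
        raise MissingPhaseError(phase, needed_by)


# ---------------------------------------------------------------------------
# phases

def phase_synth(cfg: RunConfig) -> dict:
    study = cfg.study_config()
    bundle = generate_study(study)
    ledger_rows = []
    spec = cfg.injection_spec()
    if spec is not None:
        bundle, ledger = inject_errors(bundle, spec)
        ledger_rows = [asdict(e) for e in ledger.entries]
    cfg.staging_dir.mkdir(parents=True, exist_ok=True)
    write_staging(bundle, cfg.staging_dir)
    if ledger_rows:
        import csv

        with open(cfg.staging_dir / "injection_ledger.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=["rule", "table", "row_key"], lineterminator="\n")
            writer.writeheader()
            writer.writerows(ledger_rows)
    counts = {
        "households": len(bundle.households),
        "individuals": len(bundle.individuals),
        "waves": len(bundle.waves),
        "variables": len(bundle.variables),
        "responses": len(bundle.responses),
        "injected_errors": len(ledger_rows),
    }
    _update_manifest(cfg, "synth", _digest_dir(cfg.staging_dir), counts)
    return counts


def phase_vocab(cfg: RunConfig) -> dict:
    registry = bootstrap_registry()
    cfg.vocab_dir.mkdir(parents=True, exist_ok=True)
    write_vocabulary(registry, cfg.vocab_dir)
    counts = {"concepts": len(registry), "vocabularies": len(registry.vocabularies)}
    _update_manifest(cfg, "vocab-build", _digest_dir(cfg.vocab_dir), counts)
    return counts


def _condition_rule_specs(cfg: RunConfig) -> list[dict]:
    return list((cfg.raw.get("etl") or {}).get("condition_rules") or [])


def phase_map(cfg: RunConfig) -> dict:
    _require(cfg, cfg.staging_dir, "synth", "map")
    _require(cfg, cfg.vocab_dir, "vocab-build", "map")
    study = cfg.study_config()
    bundle = load_staging(cfg.staging_dir, study.study_id)
    registry = load_vocabulary(cfg.vocab_dir)

    user_table = (cfg.raw.get("mapping") or {}).get("mapping_table")
    if user_table:
        table = load_mapping_table(user_table)
    else:
        table = synthesize_mapping_table(bundle, registry)
    score_concepts = mint_score_concepts(registry, study.instruments)
    condition_concepts = {
        rule["concept_name"]: mint_local_concept(
            registry, rule["concept_name"], "Condition"
        ).concept_id
        for rule in _condition_rule_specs(cfg)
        if rule["instrument"] in study.instruments
    }
    plan = compile_mapping_plan(bundle, registry, table, reference_date=study.reference_date)

    cfg.mapping_dir.mkdir(parents=True, exist_ok=True)
    write_mapping_table(table, cfg.mapping_dir / "mapping_table.csv")
    import csv

    with open(cfg.mapping_dir / "score_concepts.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["instrument_id", "concept_id"])
        for inst in sorted(score_concepts):
            writer.writerow([inst, score_concepts[inst]])
    with open(cfg.mapping_dir / "condition_concepts.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["concept_name", "concept_id"])
        for name in sorted(condition_concepts):
            writer.writerow([name, condition_concepts[name]])
    with open(cfg.mapping_dir / "review_queue.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["variable_id", "reason"])
        for e in plan.review_queue:
            writer.writerow([e.variable_id, e.reason])
    write_vocabulary(registry, cfg.vocab_dir)  # registry now includes minted concepts

    counts = {
        "mapped_variables": len(plan.entries),
        "review_queue": len(plan.review_queue),
        "coverage_pct": round(100 * plan.coverage, 2),
    }
    _update_manifest(cfg, "map", _digest_dir(cfg.mapping_dir), counts)
    return counts


def _load_concept_csv(path: Path) -> dict[str, int]:
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader)
        return {row[0]: int(row[1]) for row in reader}


def _etl_inputs(cfg: RunConfig):
    study = cfg.study_config()
    bundle = load_staging(cfg.staging_dir, study.study_id)
    registry = load_vocabulary(cfg.vocab_dir)
    table = load_mapping_table(cfg.mapping_dir / "mapping_table.csv")
    plan = compile_mapping_plan(bundle, registry, table, reference_date=study.reference_date)
    score_concepts = _load_concept_csv(cfg.mapping_dir / "score_concepts.csv")
    condition_concepts = _load_concept_csv(cfg.mapping_dir / "condition_concepts.csv")
    rules = tuple(
        ConditionRule(r["instrument"], r["min_score"], condition_concepts[r["concept_name"]])
        for r in _condition_rule_specs(cfg)
        if r["concept_name"] in condition_concepts
    )
    etl_config = EtlConfig(
        reference_date=study.reference_date,
        score_concepts=tuple(sorted(score_concepts.items())),
        condition_rules=rules,
    )
    return study, bundle, registry, plan, etl_config


def phase_etl(cfg: RunConfig) -> dict:
    _require(cfg, cfg.staging_dir, "synth", "etl-run")
    _require(cfg, cfg.vocab_dir, "vocab-build", "etl-run")
    _require(cfg, cfg.mapping_dir, "map", "etl-run")
    _study, bundle, registry, plan, etl_config = _etl_inputs(cfg)
    cdm = run_etl(bundle, plan, registry, etl_config)
    write_cdm(cdm, cfg.cdm_dir)
    counts = {name: len(df) for name, df in cdm.tables().items()}
    _update_manifest(cfg, "etl-run", _digest_dir(cfg.cdm_dir), counts)
    return counts


def phase_qc(cfg: RunConfig) -> dict:
    _require(cfg, cfg.cdm_dir, "etl-run", "qc-run")
    cdm = load_cdm(cfg.cdm_dir)
    _study, bundle, registry, plan, etl_config = _etl_inputs(cfg)
    qconfig = quality_config_for(plan, bundle, etl_config)
    suite = default_check_suite(qconfig)
    report = run_checks(cdm, registry, suite, qconfig)
    cfg.qc_dir.mkdir(parents=True, exist_ok=True)
    import csv

    with open(cfg.qc_dir / "results.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["check_id", "category", "context", "rows_evaluated", "rows_violating", "status"]
        )
        for r in report.results:
            writer.writerow(
                [r.check_id, r.category, r.context, r.rows_evaluated, r.rows_violating, r.status]
            )
    summarize_report(report).to_csv(cfg.qc_dir / "summary.csv", index=False, lineterminator="\n")
    applicable = [r for r in report.results if r.status != "NOT_APPLICABLE"]
    counts = {
        "checks_run": len(report.results),
        "checks_applicable": len(applicable),
        "checks_failed": sum(r.status == "FAIL" for r in applicable),
    }
    _update_manifest(cfg, "qc-run", _digest_dir(cfg.qc_dir), counts)
    return counts


def _cohort_definitions(cfg: RunConfig, registry) -> dict[str, CohortDefinition]:
    name_to_id = {c.concept_name: c.concept_id for c in registry.concepts.values()}
    defs = {}
    for spec in cfg.raw.get("cohorts") or []:
        concept_ids = tuple(spec.get("concept_ids") or ()) or tuple(
            name_to_id[n] for n in spec.get("concept_names", []) if n in name_to_id
        )
        if not concept_ids:
            raise ValueError(f"cohort {spec['cohort_id']}: no resolvable concepts")
        defs[spec["cohort_id"]] = CohortDefinition(
            cohort_id=spec["cohort_id"],
            domain=spec["domain"],
            concept_ids=concept_ids,
            min_value=spec.get("min_value"),
            max_value=spec.get("max_value"),
            restriction=spec.get("restriction", "earliest_event_only"),
        )
    return defs


def phase_cohort(cfg: RunConfig) -> dict:
    _require(cfg, cfg.cdm_dir, "etl-run", "cohort")
    _require(cfg, cfg.vocab_dir, "vocab-build", "cohort")
    cdm = load_cdm(cfg.cdm_dir)
    registry = load_vocabulary(cfg.vocab_dir)
    defs = _cohort_definitions(cfg, registry)
    cfg.analytics_dir.mkdir(parents=True, exist_ok=True)
    import csv

    counts: dict = {}
    memberships_by_id = {}
    for cid, defn in defs.items():
        members = build_cohort(cdm, defn)
        memberships_by_id[cid] = members
        counts[f"cohort_{cid}"] = len(members)
        with open(cfg.analytics_dir / f"cohort_{cid}.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["cohort_id", "person_id", "index_date"])
            for m in members:
                writer.writerow([m.cohort_id, m.person_id, m.index_date.isoformat()])
        characterize_cohort(cdm, members).to_csv(
            cfg.analytics_dir / f"characterization_{cid}.csv", index=False, lineterminator="\n"
        )

    inc = cfg.raw.get("incidence") or {}
    if inc and inc.get("targets") and inc.get("outcome") in defs:
        window = TimeAtRiskWindow(
            start_offset_days=inc.get("start_offset_days", 0),
            end_offset_days=inc.get("end_offset_days", 365),
        )
        rows = incidence_rates(
            cdm, [defs[t] for t in inc["targets"]], defs[inc["outcome"]], window
        )
        with open(cfg.analytics_dir / "incidence.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(
                [
                    "target_cohort",
                    "outcome_cohort",
                    "persons_at_risk",
                    "cases",
                    "person_years",
                    "cases_per_1000_persons",
                    "rate_per_1000_py",
                ]
            )
            for r in rows:
                writer.writerow(
                    [
                        r.target_cohort,
                        r.outcome_cohort,
                        r.persons_at_risk,
                        r.cases,
                        f"{r.person_years:.6f}",
                        "n/a" if r.cases_per_1000_persons is None else f"{r.cases_per_1000_persons:.4f}",
                        "n/a" if r.rate_per_1000_py is None else f"{r.rate_per_1000_py:.4f}",
                    ]
                )
        counts["incidence_rows"] = len(rows)

    if len(defs) >= 2:
        sequences = pathway_sequences(cdm, list(defs.values()))
        with open(cfg.analytics_dir / "pathways.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["sequence", "persons"])
            for seq in sorted(sequences):
                writer.writerow([seq, sequences[seq]])
        counts["pathway_sequences"] = len(sequences)

    _update_manifest(cfg, "cohort", _digest_dir(cfg.analytics_dir), counts)
    return counts


def phase_report(cfg: RunConfig) -> dict:
    _require(cfg, cfg.qc_dir, "qc-run", "report")
    _require(cfg, cfg.analytics_dir, "cohort", "report")
    manifest = json.loads(cfg.manifest_path.read_text(encoding="utf-8"))
    report = {
        "tool_version": manifest.get("tool_version"),
        "timestamp": cfg.clock,
        "phase_row_counts": {
            name: data.get("row_counts", {}) for name, data in manifest.get("phases", {}).items()
        },
    }
    out = cfg.workdir / "run_report.json"
    out.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    counts = {"phases_reported": len(report["phase_row_counts"])}
    _update_manifest(cfg, "report", {out.name: _digest(out)}, counts)
    return counts


_PHASE_FUNCS = {
    "synth": phase_synth,
    "vocab-build": phase_vocab,
    "map": phase_map,
    "etl-run": phase_etl,
    "qc-run": phase_qc,
    "cohort": phase_cohort,
    "report": phase_report,
}


def run_phase(cfg: RunConfig, phase: str) -> dict:
    return _PHASE_FUNCS[phase](cfg)
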