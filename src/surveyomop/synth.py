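"""Synthetic multi-wave survey staging data with controlled error injection.

The generator emulates the structure of longitudinal mental-health survey
studies: households with individuals, repeated data-collection waves, item
responses for standard screening instruments (see
:mod:`surveyomop.instruments`) and categorical covariates.  Item responses
are drawn per item from a fixed categorical distribution skewed toward low
severity; item missingness is independent per item (a missing item simply
has no response row).

:func:`inject_errors` corrupts a bundle with a known number of violations
per rule and returns a ground-truth ledger, so downstream cleaning and
quality checks can be tested for *exact* detection, rule by rule.  The
reference "today" used for future-date injection is part of the spec, never
the wall clock, so runs are reproducible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .instruments import get_instrument
from .staging import (
    StagingBundle,
    StagingHousehold,
    StagingIndividual,
    StagingResponse,
    StagingVariable,
    StagingWave,
)

__all__ = [
    "StudyConfig",
    "ErrorInjectionSpec",
    "InjectionLedger",
    "InjectionError",
    "generate_study",
    "inject_errors",
    "item_variable_id",
    "DEFAULT_REFERENCE_DATE",
]

DEFAULT_REFERENCE_DATE = dt.date(2024, 1, 1)

# Covariate label -> category list; unknown labels get generic categories.
_COVARIATE_CATEGORIES = {
    "employment_status": ("employed", "unemployed", "student", "retired"),
    "religious_affiliation": ("yes", "no"),
    "residence": ("rural", "urban"),
    "education_level": ("none", "primary", "secondary", "tertiary"),
}

_SEX_CODES = ("F", "M")
_RACE_CODES = ("R1", "R2", "R3")
_ETHNICITY_CODES = ("E1", "E2")
_MARITAL_CODES = ("M1", "M2", "M3")


@dataclass(frozen=True)
class StudyConfig:
    study_id: str = "study_01"
    n_households: int = 40
    n_individuals: int = 100
    n_waves: int = 3
    instruments: tuple[str, ...] = ("PHQ-9", "GAD-7")
    covariates: tuple[str, ...] = ("employment_status", "religious_affiliation")
    item_missingness: float = 0.02
    demographic_missingness: float = 0.05
    seed: int = 0
    first_wave_date: dt.date = dt.date(2018, 6, 1)
    wave_interval_days: int = 365
    reference_date: dt.date = DEFAULT_REFERENCE_DATE

    def __post_init__(self) -> None:
        if not (0.0 <= self.item_missingness <= 1.0):
            raise ValueError("item_missingness must be in [0, 1]")
        if not (0.0 <= self.demographic_missingness <= 1.0):
            raise ValueError("demographic_missingness must be in [0, 1]")
        if self.n_waves < 1:
            raise ValueError("n_waves must be >= 1")
        for inst in self.instruments:
            get_instrument(inst)  # fatal on unknown label


@dataclass(frozen=True)
class ErrorInjectionSpec:
    future_birth_dates: int = 0
    event_before_birth: int = 0
    null_required_ids: int = 0
    unmapped_codes: int = 0
    out_of_range_items: int = 0
    seed: int = 0
    reference_date: dt.date = DEFAULT_REFERENCE_DATE

    @property
    def total(self) -> int:
        return (
            self.future_birth_dates
            + self.event_before_birth
            + self.null_required_ids
            + self.unmapped_codes
            + self.out_of_range_items
        )


@dataclass(frozen=True)
class LedgerEntry:
    rule: str
    table: str
    row_key: str


@dataclass
class InjectionLedger:
    entries: list[LedgerEntry] = field(default_factory=list)

    def count(self, rule: Optional[str] = None) -> int:
        if rule is None:
            return len(self.entries)
        return sum(1 for e in self.entries if e.rule == rule)

    def keys(self, rule: str) -> set[str]:
        return {e.row_key for e in self.entries if e.rule == rule}


class InjectionError(ValueError):
    """Requested more corruptions than there are eligible rows."""


def item_variable_id(instrument_id: str, item_index: int) -> str:
    """Stable variable id for item ``item_index`` (0-based) of an instrument."""
    return f"{instrument_id}_item{item_index + 1:02d}"


def _severity_weights(n_categories: int) -> np.ndarray:
    # geometric decay: mild responses dominate, severe ones are rare
    w = 0.5 ** np.arange(n_categories)
    return w / w.sum()


def generate_study(config: StudyConfig) -> StagingBundle:
    """Generate one study's staging bundle; identical config => identical bundle."""
    rng = np.random.default_rng(config.seed)

    households = [
        StagingHousehold(
            household_id=f"{config.study_id}_hh{k + 1:05d}",
            location_label=f"site_{k % 5 + 1}",
            latitude=round(float(rng.uniform(-4.5, 1.5)), 6),
            longitude=round(float(rng.uniform(33.0, 40.0)), 6),
        )
        for k in range(config.n_households)
    ]

    individuals = []
    for k in range(config.n_individuals):
        hh = (
            households[int(rng.integers(0, len(households)))].household_id
            if households
            else None
        )
        age_days = int(rng.integers(18 * 365, 80 * 365))
        birth = config.first_wave_date - dt.timedelta(days=age_days)
        # identifiers, sex and birth date are always captured in the emulated
        # studies; missingness hits the optional demographic codes only
        miss = rng.random(3) < config.demographic_missingness
        individuals.append(
            StagingIndividual(
                individual_id=f"{config.study_id}_ind{k + 1:06d}",
                household_id=hh,
                sex_code=str(rng.choice(_SEX_CODES)),
                birth_date=birth,
                race_code=None if miss[0] else str(rng.choice(_RACE_CODES)),
                ethnicity_code=None if miss[1] else str(rng.choice(_ETHNICITY_CODES)),
                marital_status_code=None if miss[2] else str(rng.choice(_MARITAL_CODES)),
            )
        )

    waves = [
        StagingWave(
            wave_id=f"{config.study_id}_w{k + 1}",
            study_id=config.study_id,
            wave_index=k + 1,
            wave_date=config.first_wave_date + dt.timedelta(days=k * config.wave_interval_days),
        )
        for k in range(config.n_waves)
    ]

    variables: list[StagingVariable] = []
    for inst in config.instruments:
        defn = get_instrument(inst)
        lo, hi = defn.item_range
        allowed = tuple(str(v) for v in range(lo, hi + 1))
        for i in range(defn.n_items):
            variables.append(
                StagingVariable(
                    variable_id=item_variable_id(inst, i),
                    instrument_id=inst,
                    value_kind="categorical",
                    allowed_values=allowed,
                )
            )
    for cov in config.covariates:
        cats = _COVARIATE_CATEGORIES.get(cov, ("cat_a", "cat_b", "cat_c"))
        variables.append(
            StagingVariable(
                variable_id=cov,
                instrument_id=None,
                value_kind="categorical",
                allowed_values=tuple(cats),
            )
        )

    responses: list[StagingResponse] = []
    for ind in individuals:
        for wave in waves:
            for inst in config.instruments:
                defn = get_instrument(inst)
                lo, hi = defn.item_range
                weights = _severity_weights(hi - lo + 1)
                values = rng.choice(np.arange(lo, hi + 1), size=defn.n_items, p=weights)
                missing = rng.random(defn.n_items) < config.item_missingness
                for i in range(defn.n_items):
                    if missing[i]:
                        continue
                    responses.append(
                        StagingResponse(
                            individual_id=ind.individual_id,
                            wave_id=wave.wave_id,
                            variable_id=item_variable_id(inst, i),
                            raw_value=str(int(values[i])),
                            numeric_value=float(values[i]),
                        )
                    )
            for cov in config.covariates:
                if rng.random() < config.item_missingness:
                    continue
                cats = _COVARIATE_CATEGORIES.get(cov, ("cat_a", "cat_b", "cat_c"))
                responses.append(
                    StagingResponse(
                        individual_id=ind.individual_id,
                        wave_id=wave.wave_id,
                        variable_id=cov,
                        raw_value=str(rng.choice(cats)),
                        numeric_value=None,
                    )
                )

    return StagingBundle(
        study_id=config.study_id,
        households=households,
        individuals=individuals,
        waves=waves,
        variables=variables,
        responses=responses,
    )


def _pick(rng: np.random.Generator, pool: list, k: int, rule: str) -> list:
    if len(pool) < k:
        raise InjectionError(
            f"rule {rule}: requested {k} corruptions but only {len(pool)} eligible rows"
        )
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[int(i)] for i in sorted(idx)]


def inject_errors(
    bundle: StagingBundle, spec: ErrorInjectionSpec
) -> tuple[StagingBundle, InjectionLedger]:
    """Corrupt a copy of ``bundle`` per the spec; return it with a ledger.

    Rules never overlap: each individual is targeted by at most one rule,
    and out-of-range items are injected only on responses of untouched
    individuals, so every ledger entry corresponds to exactly one
    downstream detection or cleaning event.
    """
    rng = np.random.default_rng(spec.seed)
    out = bundle.copy()
    ledger = InjectionLedger()
    targeted: set[str] = set()
    wave_dates = sorted(w.wave_date for w in out.waves)
    index_of = {ind.individual_id: i for i, ind in enumerate(out.individuals)}

    def eligible_individuals(pred) -> list[str]:
        return [
            ind.individual_id
            for ind in out.individuals
            if ind.individual_id not in targeted and ind.individual_id != "" and pred(ind)
        ]

    # future birth dates: birth moved past the reference "today"
    pool = eligible_individuals(lambda ind: ind.birth_date is not None)
    for iid in _pick(rng, pool, spec.future_birth_dates, "future_birth_dates"):
        i = index_of[iid]
        out.individuals[i] = replace(
            out.individuals[i],
            birth_date=spec.reference_date + dt.timedelta(days=int(rng.integers(30, 1000))),
        )
        targeted.add(iid)
        ledger.entries.append(LedgerEntry("future_birth_dates", "individuals", iid))

    # events before birth: birth moved after the first wave (but never into
    # the future), so that person's wave-1 events precede their birth date
    if spec.event_before_birth:
        if not wave_dates or wave_dates[0] + dt.timedelta(days=1) > spec.reference_date:
            raise InjectionError("event_before_birth: no pre-reference wave to straddle")
        ids_with_w1 = {
            r.individual_id
            for r in out.responses
            if any(w.wave_id == r.wave_id and w.wave_date == wave_dates[0] for w in out.waves)
        }
        pool = eligible_individuals(
            lambda ind: ind.birth_date is not None and ind.individual_id in ids_with_w1
        )
        new_birth = wave_dates[0] + dt.timedelta(days=1)
        if len(wave_dates) > 1:
            new_birth = min(new_birth, wave_dates[1] - dt.timedelta(days=1))
        for iid in _pick(rng, pool, spec.event_before_birth, "event_before_birth"):
            i = index_of[iid]
            out.individuals[i] = replace(out.individuals[i], birth_date=new_birth)
            targeted.add(iid)
            ledger.entries.append(LedgerEntry("event_before_birth", "individuals", iid))

    # null required identifiers
    pool = eligible_individuals(lambda ind: True)
    for iid in _pick(rng, pool, spec.null_required_ids, "null_required_ids"):
        i = index_of[iid]
        out.individuals[i] = replace(out.individuals[i], individual_id="")
        targeted.add(iid)
        ledger.entries.append(LedgerEntry("null_required_ids", "individuals", iid))

    # source codes with no mapping
    pool = eligible_individuals(lambda ind: ind.sex_code is not None)
    for iid in _pick(rng, pool, spec.unmapped_codes, "unmapped_codes"):
        i = index_of[iid]
        out.individuals[i] = replace(out.individuals[i], sex_code="XX_UNMAPPED")
        targeted.add(iid)
        ledger.entries.append(LedgerEntry("unmapped_codes", "individuals", iid))

    # instrument item values outside the published response range
    if spec.out_of_range_items:
        item_vars = {v.variable_id for v in out.variables if v.instrument_id is not None}
        pool_idx = [
            j
            for j, r in enumerate(out.responses)
            if r.variable_id in item_vars and r.individual_id not in targeted
        ]
        for j in _pick(rng, pool_idx, spec.out_of_range_items, "out_of_range_items"):
            r = out.responses[j]
            out.responses[j] = replace(r, raw_value="99", numeric_value=99.0)
            ledger.entries.append(
                LedgerEntry(
                    "out_of_range_items",
                    "responses",
                    f"{r.individual_id}|{r.wave_id}|{r.variable_id}",
                )
            )

    assert ledger.count() == spec.total
    return out, ledger
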