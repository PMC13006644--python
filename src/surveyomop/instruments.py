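"""Psychometric instrument definitions and composite scoring.

Covers the screening instruments commonly administered in longitudinal
mental-health surveys: PHQ-9 and PHQ-5 (depression), GAD-7 (generalised
anxiety), EPDS (postnatal depression), DASS-21 (depression / anxiety /
stress), CES-D (depressive symptomatology), PCL-5 (PTSD) and the PSQ
(perceived stress).  Item codings default to the published response ranges
(most 4-point 0-3; PCL-5 five-point 0-4; PSQ four-point 1-4) and are
overridable by constructing your own :class:`InstrumentDefinition`.

Scoring is a plain item sum except the DASS-21, whose subscale and total
scores are doubled to the DASS-42 scale.  The default completeness policy
is strict: any missing item yields no total (no prorating).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "InstrumentDefinition",
    "ScoreResult",
    "STANDARD_INSTRUMENTS",
    "get_instrument",
    "score_instrument",
    "wave_scores",
]


@dataclass(frozen=True)
class InstrumentDefinition:
    instrument_id: str
    n_items: int
    item_range: tuple[int, int]  # inclusive
    subscales: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    score_rule: str = "sum"  # "sum" | "sum_times_two"

    def __post_init__(self) -> None:
        lo, hi = self.item_range
        if lo < 0 or hi < lo:
            raise ValueError(f"{self.instrument_id}: bad item_range {self.item_range}")
        for name, idx in self.subscales.items():
            if any(i < 0 or i >= self.n_items for i in idx):
                raise ValueError(f"{self.instrument_id}: subscale {name} index out of range")
        if self.score_rule not in ("sum", "sum_times_two"):
            raise ValueError(f"unknown score_rule {self.score_rule!r}")

    @property
    def multiplier(self) -> int:
        return 2 if self.score_rule == "sum_times_two" else 1

    @property
    def score_range(self) -> tuple[int, int]:
        lo, hi = self.item_range
        return (self.n_items * lo * self.multiplier, self.n_items * hi * self.multiplier)


@dataclass(frozen=True)
class ScoreResult:
    instrument_id: str
    total: Optional[int]
    subscale_totals: Mapping[str, Optional[int]]
    n_missing_items: int
    complete: bool


_DASS21_SUBSCALES = {
    # 1-based item numbers of the published DASS-21 subscales, 0-based here
    "depression": (2, 4, 9, 12, 15, 16, 20),
    "anxiety": (1, 3, 6, 8, 14, 18, 19),
    "stress": (0, 5, 7, 10, 11, 13, 17),
}

STANDARD_INSTRUMENTS: dict[str, InstrumentDefinition] = {
    d.instrument_id: d
    for d in (
        InstrumentDefinition("PHQ-9", 9, (0, 3)),
        InstrumentDefinition("PHQ-5", 5, (0, 3)),
        InstrumentDefinition("GAD-7", 7, (0, 3)),
        InstrumentDefinition("EPDS", 10, (0, 3)),
        InstrumentDefinition("DASS-21", 21, (0, 3), _DASS21_SUBSCALES, "sum_times_two"),
        InstrumentDefinition("CES-D", 20, (0, 3)),
        InstrumentDefinition("PCL-5", 20, (0, 4)),
        InstrumentDefinition("PSQ", 30, (1, 4)),
    )
}


def get_instrument(instrument_id: str) -> InstrumentDefinition:
    try:
        return STANDARD_INSTRUMENTS[instrument_id]
    except KeyError:
        raise KeyError(f"unknown instrument {instrument_id!r}") from None


def score_instrument(
    defn: InstrumentDefinition,
    items: Sequence[Optional[int]],
    *,
    prorate: bool = False,
) -> ScoreResult:
    """Score one administered instrument instance.

    ``items`` is the ordered item vector, ``None`` marking a missing item.
    Values outside the instrument's item range raise ``ValueError`` naming
    the offending index.  With ``prorate=True`` an incomplete instrument is
    scored by mean-substituting missing items (rounded); the default is the
    strict policy (missing item => no total).
    """
    if len(items) != defn.n_items:
        raise ValueError(
            f"{defn.instrument_id}: expected {defn.n_items} items, got {len(items)}"
        )
    lo, hi = defn.item_range
    present: list[int] = []
    for idx, v in enumerate(items):
        if v is None:
            continue
        if not (lo <= v <= hi):
            raise ValueError(
                f"{defn.instrument_id}: item {idx} value {v} outside range [{lo}, {hi}]"
            )
        present.append(v)
    n_missing = defn.n_items - len(present)
    complete = n_missing == 0
    mult = defn.multiplier

    def _fill(value: Optional[int]) -> Optional[float]:
        if value is not None:
            return float(value)
        if prorate and present:
            return sum(present) / len(present)
        return None

    total: Optional[int] = None
    if complete:
        total = mult * sum(present)
    elif prorate and present:
        total = round(mult * sum(sum(present) / len(present) if v is None else v for v in items))

    subscale_totals: dict[str, Optional[int]] = {}
    for name, idx in defn.subscales.items():
        vals = [_fill(items[i]) for i in idx]
        subscale_totals[name] = None if any(v is None for v in vals) else round(mult * sum(vals))

    return ScoreResult(
        instrument_id=defn.instrument_id,
        total=total,
        subscale_totals=subscale_totals,
        n_missing_items=n_missing,
        complete=complete,
    )


def wave_scores(bundle, defns: Optional[Mapping[str, InstrumentDefinition]] = None, *, prorate: bool = False):
    """Score every administered (individual, wave, instrument) instance.

    An instance exists when the individual has at least one item response
    for that instrument in that wave.  Returns
    ``{(individual_id, wave_id, instrument_id): ScoreResult}``.  Items are
    ordered by their position in the bundle's variable table.
    """
    defns = dict(STANDARD_INSTRUMENTS if defns is None else defns)
    item_index: dict[str, tuple[str, int]] = {}  # variable_id -> (instrument, position)
    counters: dict[str, int] = {}
    for var in bundle.variables:
        if var.instrument_id is None or var.instrument_id not in defns:
            continue
        pos = counters.get(var.instrument_id, 0)
        item_index[var.variable_id] = (var.instrument_id, pos)
        counters[var.instrument_id] = pos + 1

    collected: dict[tuple[str, str, str], dict[int, Optional[int]]] = {}
    for resp in bundle.responses:
        hit = item_index.get(resp.variable_id)
        if hit is None:
            continue
        inst, pos = hit
        key = (resp.individual_id, resp.wave_id, inst)
        value = None if resp.numeric_value is None else int(resp.numeric_value)
        collected.setdefault(key, {})[pos] = value

    out = {}
    for key, items_by_pos in collected.items():
        defn = defns[key[2]]
        items = [items_by_pos.get(i) for i in range(defn.n_items)]
        out[key] = score_instrument(defn, items, prorate=prorate)
    return out
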