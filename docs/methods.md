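# Methods

This note documents the data model, procedures, defaults and design
decisions behind `surveyomop`, and what the synthetic-data tests do and do
not establish about real data.

## Staging model

The staging layer is a snowflake schema for multi-wave survey studies:
households (with optional coordinates), individuals (with source-coded
demographics and birth date), data-collection waves (ordinal index plus
calendar date per study), variable definitions (instrument items or
covariates, with value kind, optional unit, allowed category values and a
diagnosis flag), and item responses (raw text plus a parsed numeric value
when the text is numeric). It is file-backed — one UTF-8 CSV per table with
a fixed header, ISO-8601 dates, empty string meaning absent — rather than a
database, so a whole study round-trips bit-exactly and runs anywhere.
Reads validate referential integrity exhaustively; rows with dangling
references are excluded and counted per table (`bundle.exclusions`), never
repaired, matching the pipeline's general posture that bad data is evidence
to preserve, not noise to patch.

## Synthetic studies

The generator emulates the *structure* of longitudinal mental-health
surveys, not their psychometrics. Defaults: 100 individuals in 40
households, 3 waves at 365-day intervals starting 2018-06-01, PHQ-9 and
GAD-7 plus two categorical covariates, 2% independent item missingness
(a missing item has no response row), 5% missingness on the optional
demographic codes (race, ethnicity, marital status). Identifiers, sex codes
and birth dates are always captured, as in the study designs emulated; birth
dates put respondents between 18 and 80 years old at wave 1. Item responses
are drawn independently per item from a geometric-decay categorical
distribution over the instrument's published response range (probability
halves per severity step, e.g. 8/15, 4/15, 2/15, 1/15 on a 0–3 item), so
low-severity answers dominate as in community screening data. All
randomness flows through one seeded NumPy generator: identical configs give
byte-identical serialised bundles.

What this does **not** emulate: inter-item correlation and factor structure,
within-person trajectories over waves, informative attrition, household
clustering of outcomes, or instrument-specific score distributions. Passing
tests therefore demonstrate the *mechanics* of the pipeline — accounting,
routing, detection, determinism — not epidemiological realism of rates or
distributions.

### Error injection

`inject_errors` corrupts a copy of a bundle with exact counts per rule and
returns a ground-truth ledger of (rule, table, row key). The reference
"today" is a config value (default 2024-01-01), never the wall clock. Rules
never overlap (one individual is targeted by at most one rule; out-of-range
items are injected only on responses of untouched individuals), so each
ledger entry resolves through exactly one downstream channel:

| rule                | injected as                                   | resolved by |
|---------------------|-----------------------------------------------|-------------|
| future_birth_dates  | birth date moved past the reference date      | ETL: birth nulled (logged), person then excluded for missing birth year |
| event_before_birth  | birth date moved between wave 1 and wave 2    | ETL: that person's wave-1 event dates nulled (logged; counted by distinct person) |
| null_required_ids   | individual identifier blanked                 | ETL: person excluded (logged); their event rows excluded as dangling |
| unmapped_codes      | sex code replaced by an unknown code          | ETL: remapped to concept 0 (logged) |
| out_of_range_items  | item response set to 99                       | QC: instrument-range plausibility check (rows pass through ETL unchanged) |

This makes "cleaned by ETL plus detected by QC equals the ledger, rule by
rule" a checkable identity, which the acceptance tests verify on a
1,000-person study with 50 injected errors.

## Vocabulary and mapping

Local concepts are minted sequentially from 2,000,000,001, keeping local and
standard id spaces disjoint by construction (the floor is the invariant; the
sequential allocation is our choice for determinism and auditability).
Minting is idempotent on (name, domain). Local concepts carry the standard
flag `'S'` and are referenced directly in `*_concept_id` fields — a
deliberate deviation from the THEMIS convention of confining custom codes to
`*_source_concept_id`, chosen because downstream cohort tools only surface
concepts used in the standard fields. Every relationship insert writes the
inverse row too, so the pairing invariant is global.

`build_fixture_vocabulary` packages a synthetic 255-concept registry
reproducing a reference composition of a harmonised mental-health concept
inventory: 227 standard (89.0%) / 28 local (11.0%), local concentrated in
Observation (20), Meas Value (6) and Measurement (2); on the standard side
Observation 108, Meas Value 69, Measurement 9, Condition 25, one concept
each in Ethnicity / Condition Status / Type Concept / Visit, and the
12-concept remainder assigned to the demographic/administrative domains
(Gender 2, Race 5, Geography 3, Metadata 2) — the only self-consistent
reading of the published per-domain percentages against N=255. Concept ids
and names in the fixture are synthetic stand-ins; only the counts carry
meaning.

Mapping is table-driven: the curated variable→concept table is an explicit
input (real mappings come from expert review), and the exact-name matcher is
opt-in only. Coverage of an empty study is defined as 1.0 to avoid a 0/0.
For synthetic runs, `synthesize_mapping_table` mints a local concept per
variable and a Meas Value answer concept per category (linked with
`Has answer`), emulating the end state of a curation pass with full
coverage. Deprecation is judged against an explicit reference date.

## ETL

Tables are written in dependency order (location → care_site/provider,
emitted header-only → person → visit_occurrence → measurement /
observation / condition_occurrence). `person_id` is assigned by
deterministic enumeration of sorted source identifiers, with the source id
retained in `person_source_value`. One visit per (person, wave) with any
response; visit start = end = wave date; all `*_type_concept_id` fields take
one configurable survey-type concept (default 32862).

Cleaning rules, in order: null/blank identifiers exclude the row (no
placeholder ids, ever); birth dates after the reference date are nulled,
after which the person fails the year-of-birth requirement and is excluded;
absent demographic codes default to concept 0 silently (the normal OMOP
convention for "no matching concept"), while present-but-unmappable codes
are remapped to 0 *and* logged as data errors; event dates preceding the
person's birth are nulled. Every exclusion/nulling writes one
`etl_error_log` row and every step an `etl_execution_summary` row with
`rows_in = rows_out + rows_excluded`; per step, `rows_excluded` equals the
log's excluded entries. On a clean bundle both the log and the review queue
are empty.

Composite scores use the strict completeness policy (any missing item → no
total; prorating by mean substitution is opt-in), so a score measurement is
emitted only for complete instances. Item values outside the instrument's
range are excluded from scoring input but flow through to the observation
table unchanged — they are data for the quality layer to flag, not ETL
faults. Condition rows come only from explicit config rules (instrument
total ≥ cut-point → condition concept) or from variables explicitly mapped
to the Condition domain; no severity thresholds are hard-coded because
published cut-points vary by instrument, population and purpose.

Instrument codings default to the published response ranges (PHQ-9, PHQ-5,
GAD-7, EPDS, CES-D: items 0–3; PCL-5: 0–4; PSQ: 1–4; DASS-21: items 0–3
with subscale and total scores doubled to the full-scale metric). PHQ-5 and
PHQ-9 are both defined as distinct instruments. All definitions are
overridable.

## Quality checks

The packaged suite (60+ checks with the default config) is a compact,
representative analogue of dashboard-style CDM checking, not a re-creation
of the full 1,500+-check catalogue. Verification = CDM-internal rules
(mandatory fields, unique keys, cell types, foreign keys, date logic, value
ranges); Validation = rules against the vocabulary registry or declared
expectations (concept domain and standard-flag agreement, demographic
concept membership). Thresholds default to 0 (any violating row fails the
check); concept id 0 is accepted by membership checks as the sanctioned
"no matching concept" value; checks over empty tables report
NOT_APPLICABLE and are excluded from every pass-rate denominator, so empty
tables are never rewarded. Percentages in the rollup are rounded to whole
percent; an empty cell renders blank.

## Analytics

Earliest-event cohorts keep one membership per person at the earliest
qualifying event date; among same-date events the smallest record id
qualifies (determinism; affects which event, not the date). Age at index
uses year of birth with missing month/day defaulting to July 1. Time at
risk is a config-driven window of day offsets from the index date, inclusive
at both ends; time is censored at the earliest of outcome or window end and
converted at 365.25 days/year. A zero person-year denominator renders the
rate as n/a. Pathways record each person's chronological sequence of first
entries into the event cohorts, with same-date firsts collapsed into an
unordered set (`{A,B}`) rather than arbitrarily ordered; sequence counts sum
to the number of persons entering at least one cohort.

## Numerical and degenerate-input choices

Floats are serialised with `repr` (shortest round-trip form) and dates as
ISO-8601, so every writer/reader pair is lossless and byte-stable. Empty
bundles produce header-only files and zero-count summary rows. The incidence
implementation is checked against an independent brute-force oracle that
walks each member's window day by day (exact agreement on persons/cases,
1e-9 on rates). Problem sizes used by the packaged tests and the acceptance
script — 1,000 persons × 3 waves for the audit study, 400 for clean-data
quality, 180 for the incidence oracle, 100 random cohort definitions — were
chosen as the smallest sizes at which every accounting identity is exercised
with all rules active several times over.

## Known limitations

No drug_exposure / procedure_occurrence / death / observation_period
derivation; no incremental ETL or database connectivity; no automated
terminology matching (the mapping table is the contract); no
concept-ancestor hierarchy; the quality suite covers the packaged CDM subset
only. Synthetic data cannot validate the clinical plausibility of mappings —
only their mechanics.
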