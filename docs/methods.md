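# Methods

## The validation problem

Budget-impact models submitted with reimbursement applications are
confidential Excel workbooks with idiosyncratic structure; what is
recoverable about them is their *parameter profile* (how many inputs in
each of the four categories: population, market share, dosage, acquisition
cost) and which optional modelling features they used. The validation
question — did the predicted gross drug budget impact match the realised
utilisation? — only requires a deterministic, monotone prediction function
expressed in those documented categories. `biaval` therefore defines one
canonical engine that any observed profile can be mapped onto, rather than
attempting to reconstruct twelve bespoke spreadsheets that were never
published.

## The gross budget-impact engine

For model year y = 1..H (H = 5 by default; model years, not calendar
years):

* eligible(y) = (P·[prevalence] + I·[incidence]) · (1+g)^(y−1) · Π fₖ,
  with prevalent pool P (persons), incident inflow I (persons/year),
  annual growth rate g, and extra multiplicative population factors
  fₖ ∈ [0,1] (diagnosis rates, line-of-therapy fractions, ...).
* Market share s(y) ∈ [0,1] is *point-in-year penetration*: with neither
  discontinuation nor a duration cap modelled,
  treated(y) = eligible(y)·s(y). When either cohort feature is on, each
  year's eligible(y)·s(y) enters as a start cohort; the cohort starting in
  year s contributes (1−d)^(y−s) person-years in year y while y−s is
  below the duration cap. This is the simplest reading consistent with
  "the percentage of the eligible population expected to receive the
  drug", and it reproduces the documented cohort worked examples exactly.
  The corresponding conservation law is per-cohort: a cohort's cumulative
  person-years never exceed its starter count times its capped duration.
  (Total person-years can legitimately exceed Σ eligible·share whenever
  patients persist across years — one patient treated for three years is
  three person-years.)
* packs per patient-year = u · 365.25 / pack_size · a · Π dosage factors,
  with daily dose u (units/day), pack size (units/pack) and adherence
  a ∈ (0,1]. 365.25 days/year is a fixed convention (configurable
  argument). Fractional packs are kept — the population-level expectation
  is the quantity of interest — with `pack_rounding='ceil_per_patient'`
  as an option.
* cost(y) = treated(y) · packs per patient-year · unit price, where unit
  price = list price · Π cost factors. With no extra cost factors this is
  exactly packs × list price.

Disabled features are pinned to neutral values at validation time
(g = 0, a = 1, d = 0, unbounded duration, zero pool/inflow), so a spec and
its feature flags can never disagree. Specs serialise to versioned JSON;
unknown keys are rejected.

The engine is monotone in every single parameter (nondecreasing except for
the discontinuation rate), which downstream oracles exploit.

### Why the extra factor lists

Observed models carry 3–91 population parameters, 5–30 market-share
parameters, 1–4 dosage parameters and 1–3 acquisition-cost parameters.
The engine's structural fields alone cannot reach those counts, so each
category accepts additional multiplicative factor parameters (comparator
switching under market share, wastage/vial-sharing under dosage and cost).
The census counts the flattened parameter records: the market-share vector
contributes one record per year (hence the modal count of five), a pack
size of exactly 1 is treated as structural (price already per unit) and
not counted, and adherence is counted under dosage when modelled.

## Probabilistic sensitivity analysis

Each PSA draw multiplies every varying parameter independently by a factor
on [1−r, 1+r], r = 0.20 by default; per-year market-share entries are
drawn independently; fractions are clamped back to their legal interval
afterwards. The agreed list price never varies unless explicitly
requested. The default distribution is uniform — a deliberately flat
choice when there is no reason to believe the truth sits at the centre of
the interval — with triangular and truncated-normal alternatives on the
same support (truncation at ±2 standard deviations). No correlation
structure is imposed. 1000 draws by default; the envelope is the
element-wise min/max of the draws (central percentile bounds are an
option, not the default, since the reference analysis reported extremes).

Randomness: one global seed; draw i uses the substream
`default_rng([seed, i])`, so increasing `n_simulations` extends the draw
set without reshuffling earlier draws, and results are reproducible
bit-for-bit.

Realised utilisation is classified per year as inside the closed interval
[min, max] ("situated between" is read inclusively — a measure-zero
boundary event, resolved conservatively), outside it, or not available
where no full 12-month realised window exists.

## Realised utilisation

Dispensing ledgers are validated pandas frames (drug, ISO year-month,
packs, list-price expenditure); duplicate drug-months are summed and
negative or malformed rows rejected with their row number. Drug years are
rolling 12-month windows anchored at the month of reimbursement
(half-open over month indices), at most five; `year_mode='calendar'`
anchors at the launch year's January instead, since published "full year"
conventions are ambiguous. Windows running past the analysis end are
masked, never partially summed into a "year".

## Accuracy metrics

error%(y) = (realised(y) − predicted(y)) / predicted(y) × 100, positive =
underprediction. The phrase "predicted as a percentage of realised" would
suggest dividing by realised, but that statistic is bounded above by 100%
and cannot express the observed +1017% extreme, while the sign convention
and both observed extremes are jointly consistent with division by
predicted; the literal variant remains available via
`formula='predicted_share_of_realised'` for sensitivity checks.

Drug classification: all unmasked years negative → overpredicted all
years; all positive → underpredicted; else mixed. A strict-majority label
(zeros count to neither side; 'tied' when equal) additionally assigns
mixed drugs to one side — this reproduces the reference six-under /
six-over split, which is otherwise underdetermined.

## Selection census

Exclusion reasons are assigned first-match in a pinned order (no model →
multiple indications → not reimbursed ≥ 12 months → hospital-only →
hepatitis C), so n_included + Σ reason counts = n_total. The *included
set* is order-invariant (each rule is a property of the record, asserted
by permutation testing); the per-reason tally is not, hence the pinned
order. "A full year" means 12 months of reimbursement at the analysis
date.

The bundled feature table marks six models with incidence while the
accompanying published prose says five; the census reports the
table-derived count and the discrepancy is left unresolved, so incidence
is excluded from the headline feature checks.

## Synthetic data generator

`SpecProfile` defaults are the observed study conditions: feature
marginals prevalence 12/12, growth 8/12, incidence 6/12, duration 3/12,
discontinuation 2/12, adherence 1/12; per-category parameter-count ranges
3–91 / 5–30 / 1–4 / 1–3 with the market-share count minimal (one per
year) two-thirds of the time. Values are drawn from launch-realistic
ranges: year-1 eligible population log-uniform on 100–100 000 (the source
pool is back-solved through the eligibility fractions, mirroring how real
population blocks cut a large source population down), uptake ramping
from 1–10% to at most 50% across the horizon, daily dose 0.25–4 units,
standard pack sizes, list price log-uniform on 10–10 000 per pack.

The forecast-error model is annual and multiplicative:
realised year total = predicted × bias × exp(σ·Z), Z ~ N(0,1), because
the validation comparisons are annual; the monthly spread (linear ramp
from launch in year 1, flat thereafter) is presentation only and sums
exactly to the annual totals. σ = 0, bias = 1 makes realised equal
predicted — the pipeline's end-to-end null — and bias b with σ = 0 gives
every year an error of exactly (b−1)×100%. In sensitivity sweeps the
lognormal shocks share seeds across σ values, so each drug-year's
realised value moves monotonically away from its prediction as σ grows,
making "accuracy degrades and coverage falls with σ" a deterministic
property at fixed seeds rather than a statistical one. The default
σ = 0.5 was chosen once as loosely consistent with the spread of the
observed twelve error trajectories (tens of percent to several hundred
percent); no distributional information about real forecast errors beyond
those trajectories is recoverable.

What the generator does *not* emulate: indication mixing, scheme-specific
rebates/fees, price cuts over time, seasonality, or correlated parameter
errors. One visible consequence: generated specs with many extra factors
give very wide PSA envelopes (dozens of independently varied parameters
compound), so synthetic coverage at moderate σ is higher than the roughly
half of drug-years the reference study saw captured — passing the
coverage tests demonstrates the machinery's correctness, not that real
envelopes are this forgiving.

## Problem sizes and numerical choices

Tests and the acceptance script run the PSA at the stated 1000 draws; the
end-to-end null uses a 12-drug portfolio with 60-month ledgers, and the
σ-sweep uses 200 replicate drugs at σ ∈ {0, 0.25, 0.5, 1.0}. Float
comparisons in tests use relative tolerances around 1e-9 for algebraic
identities; the zero-noise closure is exact up to the rounding of
spreading annual totals over twelfths. Degenerate inputs are errors, not
silent defaults: zero predicted cost (error undefined), empty registries,
all-masked error rows, start months after the analysis end.

## Known limitations

* Exact recreation of the twelve reference models is impossible by
  design — only their profiles are public; the reference tables are
  therefore fixtures for the summary operations, not outputs the engine
  re-derives.
* The engine is annual; within-year dynamics (dose titration, stockpiling)
  are out of scope.
* Net budget impact (comparator displacement, offsets) and
  rebates/fees/VAT are deliberately excluded throughout.
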