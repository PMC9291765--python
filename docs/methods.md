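# Methods

## Model and assumptions

`hcesfort` estimates the contribution of large-scale food fortification
to dietary micronutrient adequacy from household-level 7-day food
recall data.  The core assumptions are those of the apparent-intake
framework:

* Household food supplies are shared among members in proportion to
  each member's energy requirement.  Individual intake is never
  observed; "apparent intake per adult female equivalent (AFE)" is the
  household supply divided by the sum of member requirement ratios,
  standardized to a nonpregnant, nonlactating 18–29-year-old woman.
* The reference woman defines both adequacy cut-points.  She has high
  micronutrient requirements relative to energy, so a diet dense enough
  for her is dense enough for most other members.  Density inadequacy is
  `supply/energy × 1000 < CND`, with `CND = H-AR / reference energy ×
  1000`; intake inadequacy is `supply/AFE < H-AR`.  Values exactly at a
  threshold count as adequate (strict less-than), configurable.
* Food composition is constant across households, and scenario
  parameters give the *total* per-100-g content of each fortified
  vehicle.  Applying a scenario therefore replaces the vehicle's base
  value for covered nutrients; flour-containing products receive
  `flour_fraction × (flour_scenario − flour_baseline)`.  Energy is never
  altered, so coverage, quantities, and energy supplies are
  scenario-invariant by construction, and nutrient supplies are
  monotone across the packaged no-fortification → status-quo →
  improved-compliance scenarios.
* Iron is excluded from both cut-point classifications: the EAR
  cut-point logic assumes a roughly symmetric requirement distribution,
  which does not hold for iron in women.  Iron densities and intakes
  are still computed and reported.  Zinc thresholds default to the
  low-bioavailability tier (diets high in unrefined grains); the tier
  is selectable in `requirements_nutrients*.csv`.

## Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| reference energy | kcal/day | 2100 | adult woman, moderate activity; defines AFE = 1 and the CND denominator |
| pregnancy / lactation increment | kcal/day | +285 / +500 | standard additive allowances in the packaged energy table |
| H-AR per nutrient | nutrient units/day | packaged placeholders | see "Placeholder provenance" below |
| H-UL (vitamin A) | µg RAE/day | 3000 | excess-intake screen |
| outlier threshold | robust z | 3.0 | flags \|log q − median\|/(1.4826·MAD) > 3 per item |
| loess span α / degree | – | 0.75 / 2 | quadratic local fits over ⌈αn⌉ nearest points, tricube weights |
| flour fractions | proportion | bread 0.70, buns/scones 0.65, mandasi 0.50 | typical bakery formulations; editable recipe file |

### Placeholder provenance

The numeric H-AR/H-UL values, the age–sex energy bands, and the recipe
flour fractions ship as *synthetic placeholders* (files suffixed
`_synthetic`): plausible values drawn from the harmonized-requirement
literature, intended to exercise the arithmetic, not to be authoritative
for any country.  Real analyses must replace them with national tables;
every loader accepts a user file with the same schema.

## The synthetic survey generator

The generator emulates the *structure* of an HCES so the pipeline can be
validated against known ground truth:

* 136-item food list with per-100-g compositions typical of an
  eastern-African food composition table; ~20 named staples, produce,
  and animal-source foods plus low-coverage miscellaneous items.
* Consumption follows a Bernoulli gate (7-day coverage) with
  conditionally log-normal quantities — the simplest model reproducing
  the zero-inflated, right-skewed median/IQR structure of household
  food-acquisition data.  Quantities are generated per AFE and scaled by
  the household's AFE, so cleaned per-AFE medians recover the configured
  values exactly in expectation.
* Vehicle coverage and median consumption are configured per residence
  × SEP-quintile matrices; the defaults transcribe the published
  national gradients for oil, sugar, and wheat flour (national coverage
  ≈ 76% / 56% / 52% at an 18% urban share).  Wheat consumption is
  generated as a group gate and then split across flour, bread,
  buns/scones, and mandasi.
* Seasonality is multiplicative, `1 + A·sin(2π(d − φ)/365)`, applied to
  both the consumption probability and the quantity of designated
  produce items (leafy greens, mango, papaya, pumpkin, sweet potato);
  amplitude and peak day per item are recorded in the ground truth.
* SEP gradients: ordinary items carry a log-odds coverage slope in the
  household's expenditure percentile, and quantities scale as
  `exp(γ(pct − 0.5))` (γ = 0.45), so richer households eat more food and
  more animal-source food.  This produces the structural pattern that
  fortification reduces vitamin A inadequacy least in the lowest rural
  quintile — poor rural households consume too little oil and sugar to
  benefit — while flour-only nutrients barely move anywhere.
* A configurable share of records (default 30%) is emitted in
  nonstandard units (piece/pail/sachet/cup) with a packaged conversion
  table, and quantities are emitted as-purchased so the edible-portion
  path is exercised.
* Household size is uniform 1–8 with a flat demographic mix, survey
  dates are uniform over a 12-month window, weights are gamma-distributed
  around 1, and expenditures are log-normal per residence.  Weights are
  arbitrary positive numbers: no sampling frame is emulated, so
  design-based variance statements are out of scope.

What passing tests on this population do **not** show: recovery under a
real two-stage cluster design, real food-matching error, regional
composition variation, or recall biases.  The generator validates the
*arithmetic and ordering properties* of the pipeline, not survey
inference.

## Numerical choices

* **Outlier cleaning** is iterated to a fixed point: flag per item with
  the robust z on the log scale of nonzero quantities, replace flags
  with the item median, recompute median/MAD, re-flag, repeat (max 10
  rounds; typically 1–2).  Gross outliers inflate the MAD and can mask
  one another; the fixed point unmasks them and makes the operation
  exactly idempotent.  The replacement value is the median of
  non-outlying records, which keeps the fixed point self-consistent.
  Items with zero MAD (no dispersion) and zero-quantity records are
  never flagged.  Because per-item quantity distributions pool
  households of very different size (AFE 1–8) and wealth (vehicle
  medians span 3–58 g/day/AFE across strata), a ×100-multiplied record
  starting in the low tail can land inside the threshold: on the
  default population the detector catches ≳90% of such injections with
  <1% false flags, not 100% — a structural property of household-level
  data rather than a detector defect.
* **Quintile ties**: average ranks cut at rank fifths, so all households
  sharing an expenditure value share a quintile; assignment is invariant
  to row order and positive rescaling.  Urban and rural pools are
  ranked independently.
* **Loess bands**: pointwise variance uses the weighted sandwich
  `σ² (XᵀWX)⁻¹ XᵀW²X (XᵀWX)⁻¹` of the local fit with a t reference on
  the window degrees of freedom; a constant series yields zero-width
  bands.  Survey weights multiply the tricube weights by default
  (toggleable).  Windows whose ⌈αn⌉ nearest points coincide are widened
  to the nearest distinct distance with a logged warning.
* **Degenerate inputs**: records with unknown (item, unit) pairs go to a
  rejects table with reason codes instead of aborting; households with
  zero energy supply are excluded from density metrics with a logged
  reason; strata with fewer than 10 dated observations are omitted from
  seasonality output; empty strata report absent (NaN) prevalence, not
  zero.

## Design choices where the design was open

* Prevalences are household-weighted by survey weight; person-denominated
  prevalence (weight × AFE) is available via `denominator="afe"`.
* Expenditures are accepted as already inflation-adjusted; an optional
  `deflator` column divides them.  No price index is constructed.
* The wheat-flour vehicle aggregates flour, bread, buns/scones, and
  mandasi; the item list is configurable.
* Folate is handled in µg as printed in the scenario table (no DFE
  conversion); fortificant retention through baking is not modeled
  beyond the recipe fractions.
* Per-AME analysis uses the same machinery by flagging a different
  reference row in the energy table.

## Problem sizes

The packaged test suite validates parameter recovery on a single
10,000-household population (fixed seed) and scenario ordering on 1,000
households; the acceptance script regenerates a 10,000-household
population from the command-line seed.  These sizes give binomial
sampling error well inside the stated recovery tolerances (±1.5 points
on national coverage, ±10% on per-stratum consumer medians, ±30 days on
seasonal peaks).

## Known limitations

Intra-household distribution is proportional-to-energy only; cooking
losses, fortificant decay along the supply chain, partially fortified
market mixtures, and food away from home are not modeled; composition
is spatially constant; no design-based variance estimation.  These
mirror the standard caveats of HCES-based adequacy modeling.
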