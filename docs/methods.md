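# Methods

## What the engine computes

bioreach is production-consumption accounting, not statistical inference:
every output is a deterministic function of the input parameter set. The
central assumption chain is

1. farmers of the biofortified variety save seed at the same rate as
   farmers of the conventional crop (phase 1's FSS back-calculation);
2. area harvested is an acceptable — and conservative — proxy for area
   planted, since weather, pests and disease make farmers harvest fewer
   hectares than they plant;
3. national food-balance deduction shares (seed, feed, post-harvest losses)
   apply equally to the biofortified harvest;
4. the marketed surplus is actually consumed, at a per-capita rate set by
   the replacement scenario.

Because almost no data exist on how much of an off-farm consumer's intake
is biofortified, the off-farm estimate is a *range*: the full-replacement
scenario (r = 1.0) bounds reach from below (each consumer absorbs a full
intake's worth of supply), the half-replacement scenario (r = 0.5) doubles
the population the same tonnage can cover. Replacement is a continuous
parameter; the two conventional scenarios are config presets, not code
paths.

## The farm-saved-seed ratio

Source descriptions of this quantity are ambiguous between "ratio of
farm-saved seed to total seed *produced*" and "proportion of FSS to total
seed *used*". The bundled worked examples are arithmetically consistent
only with the former, so the engine computes `1F = (1D − 1E) / 1E` with
denominator = commercial seed production. The ratio can exceed 1 (it is
~6.4 for Nigerian cassava stems, where almost all planting material is
farm-saved); it is not a fraction.

## Units

A closed vocabulary with declared conversions only (kg↔MT ×1000; annual
kg/person ↔ daily g/person ×1000/365; percent↔fraction). Cassava planting
material is counted in bundles of stems with a bundles/ha seed rate;
bundles never convert to mass, and nothing requires them to: the seed-side
arithmetic (1A–1H, 2B) stays in bundles and crosses to tonnes only through
the per-hectare yield.

## Rounding policy

All phases chain full floating precision; rounding happens once, at
reporting, half-up (ties away from zero): integers for counts, tonnages and
coverage percent, one decimal for the FSS ratio, yield and household size,
three decimals for deduction fractions. Rounding intermediates would
compound error across the five phases — the bundled examples demonstrate
this, since their published tables print rounded intermediates that
disagree with their own chained cells by a few units in the last digit.

## Printed values and precise overrides

Each config parameter stores the value as published (`value`) and
optionally the unrounded working value (`value_precise`) when the published
arithmetic demonstrably used one. In the bundled fixtures this applies to
the food-balance deduction shares (published as whole percents; the precise
totals are recovered from each column's own harvest → edible-supply ratio)
and to national per-capita intakes (published as integers; e.g. 246.9 kg/y
for rice in Bangladesh, recovered from the mutually consistent marketed
surplus and off-farm population cells). The three-way split of the precise
deduction total across seed/feed/losses is not identifiable from the
worked examples — only the sum enters any computation — so the precise
values are allocated in proportion to the published whole percents.

The 2023 Nigerian cassava yield is itself a derived input: no farmer survey
ran that year, so the 2022 survey yield (8.2 MT/ha) is carried forward by
the 2022→2023 change in the national reference yield series
(6.0145 → 6.3459 MT/ha), giving 8.2 × 1.0551 = 8.65 MT/ha (the
`adjust_yield` operation; the fixture stores the published 8.7 with the
precise product as override).

## Degenerate inputs: clamp and flag, never crash

Two physically awkward intermediates occur in realistic configurations and
are clamped with recorded warnings instead of raising: a negative raw FSS
ratio (commercial seed production exceeding estimated seed use) clamps to
zero, and on-farm consumption exceeding the edible supply clamps the
marketed surplus to zero. Coverage above 100% and reach above the national
population are reported with plausibility flags. Configuration validation
is total: a config either parses into a valid object or produces the
complete list of violations, each naming its parameter ID.

## The household growing model

Where the number of growing households (3B) is not supplied directly, it is
derived from seed-channel records: one seed pack sold = one acquiring
household where pack counts exist, otherwise channel quantity ÷ a typical
purchase size. Acquirers accumulate with farmer-to-farmer diffusion d and
attrition a as `H_t = H_{t−1}(1+d)(1−a) + A_t`. Within a year diffusion is
applied before attrition; whether public-distribution recipients attrit at
the same rate as purchasers is likewise a config-level assumption (all
channels are pooled by default). Both rates are survey-derived inputs with
no package defaults beyond 0. The bundled fixtures supply 3B directly.

## The seed-share (full-mixing) cross-check

`alternative_seed_ratio_method` replaces the replacement-fraction
assumption with full mixing: the biofortified share of seed use
(s = 1H/1D) is taken as the biofortified share of every consumer's intake,
so the off-farm population is `4A × 1000 / (s × 4B)`. Dilution makes the
per-capita biofortified intake small and the implied population large; a
reach above the national population is flagged as the signal that full
mixing is implausible for that crop. For the bundled Nigerian cassava
example the method yields ≈224.7 million people — 98.6% of the national
population, implausibly high but, from these inputs, just below the
flagging threshold; the published account of the same calculation reports
it exceeding the population, a difference attributable to input revisions
(national population estimates for Nigeria were revised upward) that
cannot be reconstructed from the published figures alone.

## Plausibility bounds for daily intake

`intake_plausibility` converts annual kg/person to g/day (×1000/365) and
flags values outside 100–600 g/day by default. The bounds are configurable;
the default upper bound is set so that survey artefacts of the kind that
motivate the check (e.g. a reported 259 kg/y ≈ 710 g/day staple intake)
are flagged, while the highest credible national staple supplies
(~500 g/day) are not.

## Sensitivity

`reporting.sensitivity` is deterministic one-at-a-time finite-difference
analysis: the pipeline is linear in most inputs, so elasticities are exact
for scale parameters (household size → farming population elasticity 1.0)
and hyperbolic for intakes (off-farm population elasticity −1/(1+p) for a
+p perturbation of the national intake). No Monte-Carlo propagation is
attempted because the input uncertainties are qualitative (source
disagreement, not sampling error).

## Randomized configurations and what tests show

`fixtures.random_config(seed)` draws schema-valid parameter sets whose
ranges bracket the bundled ones by roughly an order of magnitude either
way, constructed so the farming population's demand stays within the
edible supply (clamping paths are tested separately with targeted inputs).
Property tests check mass balance (3E + 4A = 2H), exact scenario scaling
(4C at r = 0.5 is twice 4C at r = 1), monotonicity (reach non-increasing
in national intake, non-decreasing in yield and commercial seed), and
agreement with an independent straight-line worksheet recomputation on 200
seeded configs. These demonstrate internal correctness of the accounting,
not external validity: the generator produces internally consistent
economies and says nothing about how well real seed-rate, yield or
food-balance statistics describe a given country.

## Known limitations

- Imports and exports of the crop are not modelled (schema fields are
  reserved); for the bundled country-crop combinations trade is minimal.
- The engine cannot detect double counting of people across crops beyond
  the explicit overlap adjustment (`overlap_adjusted_reach`).
- Off-farm reach inherits all the uncertainty of the replacement-fraction
  assumption; the two scenarios bound, not estimate, it.
- Food-balance deduction shares and per-capita supplies are national
  means; sub-national heterogeneity in consumption is not represented.
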