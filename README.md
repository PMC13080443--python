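# bioreach

**bioreach** estimates how many people eat a biofortified staple crop in a
year (*reach*) and what share of a country's population that is
(*coverage*), from seed-system, agricultural-production and food-balance
data. It is aimed at managers of biofortification programs, nutrition
policymakers and researchers who need routine, reproducible reach/coverage
numbers for crops whose biofortified varieties often cannot be identified
in household surveys (zinc rice, zinc wheat, and other "invisible-trait"
crops).

## The model

Everything is deterministic accounting in five phases, computed in full
floating precision and rounded only at reporting time. With parameters
keyed by phase and letter (`1A` … `5C`):

**Phase 1 — seed availability.** Commercial biofortified seed production
(`1A`) understates what farmers plant, because farmers also save seed from
the previous harvest. Total seed use is back-calculated from area and
agronomic seed rate, `1D = 1B × 1C`; the farm-saved-seed (FSS) ratio is the
excess of use over commercial production relative to production,
`1F = max(0, (1D − 1E)/1E)`; assuming growers of the biofortified variety
save seed at the same rate, `1G = 1A × 1F` and total biofortified seed
planted is `1H = 1A + 1G`.

**Phase 2 — production.** Area planted `2B = 1H / seed rate`, harvest
`2D = 2B × yield (2C)`, and the edible supply after food-balance deductions
for next-season seed, animal feed and post-harvest losses,
`2H = 2D × (1 − 2E − 2F − 2G)`.

**Phase 3 — on-farm consumption.** Farming population
`3D = households (3B) × household size (3C)`; tonnage retained for own
consumption `3E = 3D × annual per-capita on-farm intake (3A) / 1000`.

**Phase 4 — off-farm consumption.** Marketed surplus `4A = 2H − 3E`. Under
a replacement scenario `r` (by default *full*, r = 1, and *half*, r = 0.5),
off-farm consumers obtain a fraction `r` of their national per-capita crop
intake (`4B`) from the biofortified variety, so the market supply feeds
`4C = 4A × 1000 / (r × 4B)` people.

**Phase 5 — reach and coverage.** `5A = 3D + 4C` and
`5C = 100 × 5A / national population (5B)`.

Around the core sit: a household growing model (`3B` from seed-pack sales
with farmer-to-farmer diffusion and attrition,
`H_t = H_{t−1}(1+d)(1−a) + A_t`); a seed-share (full-mixing) cross-check
for off-farm reach; a reference-series yield adjustment; a daily-intake
plausibility check; an overlap adjustment for multi-crop reach; and
one-at-a-time sensitivity analysis. Parameter sets are YAML/JSON
configurations in which every value carries a unit and a provenance tag.

## Worked example

Four country-crop parameter sets for 2023 ship with the package
(`bangladesh_zinc_rice_2023`, `pakistan_zinc_wheat_2023`,
`nigeria_vita_maize_2023`, `nigeria_vita_cassava_2023`):

```python
from bioreach import load_fixture, run_pipeline, render_table

result = run_pipeline(load_fixture("bangladesh_zinc_rice_2023"))
print(render_table([result]))
```

```text
                                                    Bangladesh rice 2023
parameter
1A  Biofortified seed produced (MT or bundles)                     7,244
1B  Total area harvested (ha)                                 11,641,645
1C  Seed rate (kg or bundles/ha)                                      30
1D  Total quantity of seed used (MT or bundles)                  349,249
1E  Total seed produced (MT or bundles)                          146,708
1F  Ratio farm-saved seed / total seed produced                      1.4
1G  Farm-saved biofortified seed (MT or bundles)                  10,001
1H  Total biofortified seed used (MT or bundles)                  17,245
2B  Area planted with biofortified crop (ha)                     574,829
2D  Production of the biofortified crop (MT)                   3,219,045
2H  Edible supply available for consumption (MT)               2,640,819
3D  Farming population (#)                                     7,146,493
3E  On-farm consumption (MT)                                   1,336,394
4A  Off-farm consumption (MT)                                  1,304,425
4C.1  Population consuming off-farm, scenario 1 (#)            5,283,210
4C.2  Population consuming off-farm, scenario 2 (#)           10,566,420
5A.1  Reach, scenario 1 (#)                                   12,429,703
5A.2  Reach, scenario 2 (#)                                   17,712,913
5C.1  Coverage, scenario 1 (%)                                         7
5C.2  Coverage, scenario 2 (%)                                        10
```

(abridged; the full table has one row per parameter ID). Reading: 17,245 MT
of zinc-rice seed was planted in 2023, producing 3.22 million MT of grain
of which 2.64 million MT remained edible after deductions. The 2.55 million
growing households (7.1 million people) retained 1.34 million MT; the
1.30 million MT marketed surplus feeds 5.3 million people if off-farm
consumers source all of their rice intake from the biofortified variety
(scenario 1) or 10.6 million if half (scenario 2). Reach is therefore
12.4–17.7 million people, i.e. 7–10% national coverage.

The same is available from a shell:

```bash
bioreach validate my_config.yaml
bioreach run my_config.yaml --out results/ --alt-method
bioreach report results/
bioreach sweep my_config.yaml --param 3C --range 2:8:7
```

The seed-share cross-check (`--alt-method` or
`bioreach.alternative_seed_ratio_method`) assumes the biofortified crop is
fully mixed into the market supply; for Pakistan wheat it prints
`share=35.1% reach=237,908,372 coverage=96.1%`, and a reach above the
national population is flagged as implausible rather than raised.

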