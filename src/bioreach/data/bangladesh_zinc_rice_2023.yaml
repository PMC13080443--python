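# Zinc-biofortified rice, Bangladesh, 2023.
# `value` holds the published (rounded) figure; `value_precise` restores the
# unrounded working value where the published arithmetic demonstrably used one
# (whole-percent food-balance deductions; integer per-capita intake).
metadata:
  country: Bangladesh
  crop: rice
  nutrient: zinc
  year: 2023
parameters:
  "1A":
    value: 7244
    unit: MT
    provenance: {source_type: primary_survey, citation: "seed producer census", year: 2023}
  "1B":
    value: 11641645
    unit: ha
    provenance: {source_type: faostat, citation: "Crops and livestock products", year: 2023}
  "1C":
    value: 30
    unit: kg_per_ha
    provenance: {source_type: publication, citation: "BINA agronomic recommendation"}
  "1E":
    value: 146708
    unit: MT
    provenance: {source_type: publication, citation: "Ministry of Agriculture seed statistics", year: 2023}
  "2C":
    value: 5.6
    unit: MT_per_ha
    provenance: {source_type: primary_survey, citation: "farmer monitoring survey", year: 2023}
  "2E":
    value: 2
    value_precise: 1.8908061
    unit: percent
    provenance: {source_type: faostat, citation: "Food balances: seed", year: 2023}
  "2F":
    value: 13
    value_precise: 12.2902397
    unit: percent
    provenance: {source_type: faostat, citation: "Food balances: feed", year: 2023}
  "2G":
    value: 4
    value_precise: 3.7816122
    unit: percent
    provenance: {source_type: faostat, citation: "Food balances: losses", year: 2023}
  "3A":
    value: 187
    unit: kg_per_person_year
    provenance: {source_type: primary_survey, citation: "farmer monitoring survey (median)", year: 2023}
  "3B":
    value: 2552319
    unit: households
    provenance: {source_type: primary_survey, citation: "household growing model", year: 2023}
  "3C":
    value: 2.8
    unit: persons
    provenance: {source_type: publication, citation: "Household Income and Expenditure Survey", year: 2022}
  "4B":
    value: 247
    value_precise: 246.9
    unit: kg_per_person_year
    provenance: {source_type: faostat, citation: "Food balances: per-capita food supply", year: 2023}
  "5B":
    value: 171466990
    unit: persons
    provenance: {source_type: worldbank, citation: "World Development Indicators", year: 2023}
scenarios:
  - {label: full replacement, replacement_fraction: 1.0}
  - {label: half replacement, replacement_fraction: 0.5}
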