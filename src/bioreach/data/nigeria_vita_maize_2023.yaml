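# Vitamin-A (orange) maize, Nigeria, 2023.
metadata:
  country: Nigeria
  crop: maize
  nutrient: vitamin A
  year: 2023
parameters:
  "1A":
    value: 13282
    unit: MT
    provenance: {source_type: primary_survey, citation: "seed producer census", year: 2023}
  "1B":
    value: 5700000
    unit: ha
    provenance: {source_type: faostat, citation: "Crops and livestock products", year: 2023}
  "1C":
    value: 20
    unit: kg_per_ha
    provenance: {source_type: publication, citation: "IITA agronomic recommendation"}
  "1E":
    value: 60000
    unit: MT
    provenance: {source_type: publication, citation: "national seed sector study", year: 2023}
  "2C":
    value: 1.5
    unit: MT_per_ha
    provenance: {source_type: primary_survey, citation: "farmer monitoring survey", year: 2023}
  "2E":
    value: 1
    value_precise: 1.0027692
    unit: percent
    provenance: {source_type: faostat, citation: "Food balances: seed", year: 2023}
  "2F":
    value: 36
    value_precise: 36.0996917
    unit: percent
    provenance: {source_type: faostat, citation: "Food balances: feed", year: 2023}
  "2G":
    value: 5
    value_precise: 5.0138461
    unit: percent
    provenance: {source_type: faostat, citation: "Food balances: losses", year: 2023}
  "3A":
    value: 20
    unit: kg_per_person_year
    provenance: {source_type: primary_survey, citation: "farmer monitoring survey (median)", year: 2023}
  "3B":
    value: 1962832
    unit: households
    provenance: {source_type: primary_survey, citation: "household growing model", year: 2023}
  "3C":
    value: 9.1
    unit: persons
    provenance: {source_type: primary_survey, citation: "farmer monitoring survey", year: 2023}
  "4B":
    value: 31
    value_precise: 30.9
    unit: kg_per_person_year
    provenance: {source_type: faostat, citation: "Food balances: per-capita food supply", year: 2023}
  "5B":
    value: 227882945
    unit: persons
    provenance: {source_type: worldbank, citation: "World Development Indicators", year: 2023}
scenarios:
  - {label: full replacement, replacement_fraction: 1.0}
  - {label: half replacement, replacement_fraction: 0.5}
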