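# Vitamin-A (yellow) cassava, Nigeria, 2023.
# Cassava planting material is counted in bundles of stems, never converted to
# mass; yield is per hectare so no conversion is needed anywhere.
# No farmer survey was run in 2023: the 2022 survey yield (8.2 MT/ha) is
# carried forward with the 2022->2023 change in the national reference yield
# series (6.0145 -> 6.3459 MT/ha), i.e. 8.2 x 6.3459/6.0145 = 8.6518 MT/ha,
# stored as the precise override under the published rounded 8.7.
metadata:
  country: Nigeria
  crop: cassava
  nutrient: vitamin A
  year: 2023
parameters:
  "1A":
    value: 4845831
    unit: bundles
    provenance: {source_type: primary_survey, citation: "stem multiplier census", year: 2023}
  "1B":
    value: 9878773
    unit: ha
    provenance: {source_type: faostat, citation: "Crops and livestock products", year: 2023}
  "1C":
    value: 60
    unit: bundles_per_ha
    provenance: {source_type: publication, citation: "IITA agronomic recommendation"}
  "1E":
    value: 79820000
    unit: bundles
    provenance: {source_type: publication, citation: "National Agricultural Seeds Council", year: 2023}
  "2C":
    value: 8.7
    value_precise: 8.65182143
    unit: MT_per_ha
    provenance: {source_type: primary_survey, citation: "farmer monitoring survey 2022, reference-series adjusted to 2023"}
  "2E":
    value: 0
    unit: percent
    provenance: {source_type: faostat, citation: "Food balances: seed (stems are not part of the harvested root)", year: 2023}
  "2F":
    value: 20
    value_precise: 20.2078932
    unit: percent
    provenance: {source_type: faostat, citation: "Food balances: feed", year: 2023}
  "2G":
    value: 18
    value_precise: 18.1871039
    unit: percent
    provenance: {source_type: faostat, citation: "Food balances: losses", year: 2023}
  "3A":
    value: 89
    unit: kg_per_person_year
    provenance: {source_type: primary_survey, citation: "farmer monitoring survey (median)", year: 2018}
  "3B":
    value: 2236726
    unit: households
    provenance: {source_type: primary_survey, citation: "household growing model", year: 2023}
  "3C":
    value: 5.6
    unit: persons
    provenance: {source_type: primary_survey, citation: "farmer monitoring survey", year: 2018}
  "4B":
    value: 162
    value_precise: 161.6
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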