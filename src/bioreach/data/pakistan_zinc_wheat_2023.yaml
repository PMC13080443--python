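# Zinc-biofortified wheat, Pakistan, 2023.
# Pakistan substitutes national sources for two survey inputs: the FAOSTAT
# per-capita supply stands in for the on-farm intake (3A), and the rural mean
# household size comes from the 2023 census — both are config choices carried
# in provenance, not special code paths.
metadata:
  country: Pakistan
  crop: wheat
  nutrient: zinc
  year: 2023
parameters:
  "1A":
    value: 179486
    unit: MT
    provenance: {source_type: primary_survey, citation: "seed producer census", year: 2023}
  "1B":
    value: 9032688
    unit: ha
    provenance: {source_type: faostat, citation: "Crops and livestock products", year: 2023}
  "1C":
    value: 120
    unit: kg_per_ha
    provenance: {source_type: publication, citation: "national agronomic recommendation"}
  "1E":
    value: 511379
    unit: MT
    provenance: {source_type: publication, citation: "Pakistan Economic Survey", year: 2023}
  "2C":
    value: 3.5
    unit: MT_per_ha
    provenance: {source_type: primary_survey, citation: "farmer monitoring survey", year: 2023}
  "2E":
    value: 4
    value_precise: 4.0220800
    unit: percent
    provenance: {source_type: faostat, citation: "Food balances: seed", year: 2023}
  "2F":
    value: 2
    value_precise: 2.0110400
    unit: percent
    provenance: {source_type: faostat, citation: "Food balances: feed", year: 2023}
  "2G":
    value: 4
    value_precise: 4.0220800
    unit: percent
    provenance: {source_type: faostat, citation: "Food balances: losses", year: 2023}
  "3A":
    value: 103
    unit: kg_per_person_year
    provenance: {source_type: faostat, citation: "Food balances: per-capita food supply", year: 2023}
  "3B":
    value: 3276066
    unit: households
    provenance: {source_type: primary_survey, citation: "household growing model", year: 2023}
  "3C":
    value: 6.3
    unit: persons
    provenance: {source_type: census, citation: "Population census, rural mean", year: 2023}
  "4B":
    value: 103
    unit: kg_per_person_year
    provenance: {source_type: faostat, citation: "Food balances: per-capita food supply", year: 2023}
  "5B":
    value: 247504495
    unit: persons
    provenance: {source_type: worldbank, citation: "World Development Indicators", year: 2023}
scenarios:
  - {label: full replacement, replacement_fraction: 1.0}
  - {label: half replacement, replacement_fraction: 0.5}
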