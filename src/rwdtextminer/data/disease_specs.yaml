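# Eight target diseases with manually curated ICD-10 code (range) lists.
# Ranges like E10-14 expand to E10..E14; matching is by code prefix, so
# subcategories (e.g. C509 under C50) are included.  Signature drug lists
# (ingredient concepts selected via ATC codes) are deployment-specific and
# left empty here: an empty list makes the medication-order source yield
# the empty set.
diseases:
  - name: "Alzheimer's disease"
    icd: [G300, G301, G308, G309]
    drugs: []
  - name: "Breast cancer"
    icd: [C50]
    drugs: []
  - name: "Diabetes"
    icd: [E10-14]
    drugs: []
  - name: "HIV infection"
    icd: [B20-24]
    drugs: []
  - name: "Hypercholesterolemia"
    icd: [E780]
    drugs: []
  - name: "Hypertension"
    icd: [I10-15]
    drugs: []
  - name: "Parkinson's disease"
    icd: [A521, G20, G211, G213, G214, G219]
    drugs: []
  - name: "Rheumatism"
    icd: [M123, M080, M05, M06]
    drugs: []
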