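# Plausibility configuration: value ranges per measurement concept (in the
# concept's display unit), birth-year bounds and the post-death grace period.
# concept_id values refer to the bundled synthetic vocabulary fixture.
birth_year:
  min: 1900
  max: 2021
post_death_grace_days: 0
extraction_date: "2021-06-30"
measurements:
  - {concept_id: 45200001, canonical: creatinine, unit: "mg/dL", min: 0.2, max: 15}
  - {concept_id: 45200002, canonical: potassium, unit: "mmol/L", min: 1.5, max: 8}
  - {concept_id: 45200003, canonical: crp, unit: "mg/L", min: 0, max: 300}
  - {concept_id: 45200004, canonical: glucose, unit: "mmol/L", min: 2, max: 30}
  - {concept_id: 45200005, canonical: hemoglobin, unit: "g/dL", min: 4, max: 25}
  - {concept_id: 45200006, canonical: sodium, unit: "mmol/L", min: 110, max: 170}
  - {concept_id: 45300001, canonical: poids, unit: kg, min: 20, max: 300}
  - {concept_id: 45300002, canonical: taille, unit: cm, min: 50, max: 230}
  - {concept_id: 45300003, canonical: frequence cardiaque, unit: bpm, min: 20, max: 250}
  - {concept_id: 45300004, canonical: pa systolique, unit: mmHg, min: 50, max: 260}
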