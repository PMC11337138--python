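# caretl

**Primary-care EHR exports → OMOP CDM v5.4, as a tested, reusable ETL toolkit.**

Primary-care software accumulates years of consultations, prescriptions,
laboratory results and free-text notes in proprietary, per-vendor structures.
Reusing those data for audit or observational research requires standardizing
both the *structure* (tables and columns) and the *semantics* (local codes and
labels) into a common data model. `caretl` implements that pipeline for a
hierarchical per-patient XML export of the kind produced by French
primary-care EHR software, targeting the OHDSI OMOP Common Data Model v5.4:

* **Synthetic source generation** — a generator emulates the source export
  (four-step consultations, laboratory-specific analyte spellings such as
  `creatinine` vs `create`, CIP-coded prescriptions, partly ICD-10-coded
  histories, deaths) and writes a ground-truth manifest, so the whole chain is
  testable without any patient data.
* **Extraction and profiling** — lossless parsing into staging tables plus a
  scan report (per-field types, null fractions, value frequencies).
* **Semantic mapping** — items classified into four difficulty levels
  (1: already a standard concept; 2: a standard mapping exists, e.g.
  ATC → RxNorm; 3: structured but mapped manually; 4: free text), label
  normalization (accents, punctuation, leading line numbers, abbreviation
  expansion such as CRP → C-reactive protein, stopwords), two-hop drug mapping
  CIP → ATC → RxNorm, dual-annotator reconciliation scored with Cohen's
  κ = (p_o − p_e)/(1 − p_e), local concepts registered with ids
  > 2,000,000,000 and linked by `Maps to` relationships, and a coverage report
  (mapped concepts and records, n/N with percentages to one decimal).
* **Structural mapping** — PERSON, VISIT_OCCURRENCE (ambulatory primary-care
  visits, concept 38004247), MEASUREMENT (biometrics vs laboratory, type
  concept 32856), DRUG_EXPOSURE, NOTE, OBSERVATION, DEATH, LOCATION, PROVIDER,
  CARE_SITE, plus derived OBSERVATION_PERIOD and DRUG_ERA (ingredient-level,
  30-day persistence window).
* **Constraint-enforced loading** into SQLite with itemized rejections.
* **Kahn-framework quality checks** (Conformance / Completeness /
  Plausibility), validated against a closed set of injectable defects.
* **Validation queries and dashboard export** — five source-vs-warehouse
  queries (activity, prescriptions, laboratory) checked against the
  generator's manifest, and the three datasets a practice-feedback dashboard
  consumes.

## Worked example

```python
from caretl import GeneratorConfig, run_pipeline

res = run_pipeline(GeneratorConfig(n_patients=20, seed=3))
print(res.manifest.true_n_consultations)
print(res.kappa)
print(res.quality_summary)
print(res.validation)
```

prints

```
597
KappaResult(p_o=0.8695652173913043, p_e=0.054820415879017016, kappa=0.862,
            n_items=23, n_disagreements=3)
{'Conformance': {'pass': 9, 'fail': 0}, 'Completeness': {'pass': 6, 'fail': 0},
 'Plausibility': {'pass': 7, 'fail': 0}}
{'q1': {'dr-01': 2, 'dr-02': 3, 'dr-03': 1, 'dr-04': 4, 'dr-05': 2,
        'dr-06': 5, 'dr-07': 2, 'dr-08': 1}, 'q2': 597, 'q3': 20, 'q4': 20, 'q5': 3}
```

The 20 synthetic patients produced 597 consultations, all of which became
visit rows. The two annotators of the bundled mapping worksheet disagreed on
3 of 23 level-3 items (κ = 0.862, substantial chance-corrected agreement); a
third-expert adjudication settled each disagreement. Every Kahn quality check
passes on this defect-free build, and the five validation queries — patients
per physician, consultation count, patients exposed to metformin and to
ramipril, patients with a potassium value above 5 mmol/L — match the source
ground truth exactly (`res.concordance.all_match` is `True`).

The same stages are available as a CLI:

```bash
caretl generate --seed 7 --out export/
caretl extract --in export/ --out staging/
caretl map --staging staging/ --ledger ledger.csv
caretl build --staging staging/ --ledger ledger.csv --cdm cdm.db --era-window 30
caretl check --cdm cdm.db --out qc/
caretl report --cdm cdm.db --cutoff 2021-06-30 --out dash/
```

## Layout

* `src/caretl/` — library modules (`synthetic_source`, `extract`,
  `vocabulary`, `mapping`, `cdm_transform`, `cdm_store`, `quality`,
  `validate_report`, `pipeline`, `cli`).
* `src/caretl/data/` — synthetic vocabulary fixture, annotation worksheet,
  normalization resources, plausibility configuration (see its README).
* `docs/xml_schema.md` — the versioned source-export schema.
* `docs/methods.md` — models, conventions, parameter choices, limitations.
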