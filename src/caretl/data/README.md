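# Bundled configuration and fixture data

- `CONCEPT.csv`, `CONCEPT_RELATIONSHIP.csv`, `VOCABULARY.csv` — a **synthetic**
  vocabulary fixture standing in for an OHDSI Athena download. Concept ids in
  the 451xxxxx–457xxxxx block are invented; only a handful of well-known ids
  (8507/8532 gender, 38004247 ambulatory primary-care visit, 32817/32856/32838
  type concepts) reuse their published values. Not suitable for real mapping
  work.
- `mappings.csv` — the dual-annotator semantic-mapping worksheet for the
  level-3 items emitted by the synthetic source generator (two independent
  concept choices per normalized label, plus a third-expert adjudication where
  they disagree).
- `abbreviations.csv`, `stopwords_fr.txt` — label-normalization resources
  (French defaults plus the English stopwords of/to/an).
- `plausibility.yaml` — plausibility ranges per measurement concept, birth-year
  bounds, extraction date and the post-death grace period.
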