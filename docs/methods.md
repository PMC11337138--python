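# Methods

## The transformation problem

A primary-care EHR stores each patient as a hierarchical document: a
consultation is recorded in four steps (free-text reason for the visit,
free-text interview, structured biometric examination, and an outcome
carrying an optional free-text diagnosis, CIP-coded drug prescriptions,
referrals and vaccination notes). Laboratory panels arrive from external
laboratories that each use their own variable spellings and unit notations;
medical histories are partly ICD-10-coded and mostly free text. The toolkit
transforms such exports into an OMOP CDM v5.4 warehouse in two coupled
passes: *semantic* mapping (local vocabulary → standard concepts) and
*structural* mapping (source entities → CDM tables), followed by loading,
quality assessment and validation.

## Semantic mapping

**Difficulty levels.** Every distinct source item is classified:
level 1 — the item's code is itself a standard concept (ICD-10 codes in the
fixture, the ambulatory visit concept); level 2 — a standard mapping already
exists in the vocabulary (`Maps to`, `ATC to RxNorm`); level 3 — structured
but requiring manual mapping (laboratory and biometric labels, units, sex
values, CIP codes); level 4 — free text, out of mapping scope and stored
verbatim in NOTE. `CIP to ATC` links are deliberately *not* treated as
level-2 evidence: they are the site's own mapping artifact, so CIP items
remain level 3 while the ATC codes they reach are level 2.

**Label normalization** applies, in order: Unicode compatibility folding
with accent stripping; removal of a leading chapter/line number; replacement
of punctuation and special characters by spaces (intra-word hyphens are
kept, so `C-reactive protein` survives); whole-token abbreviation expansion
(`CRP` → `C-reactive protein`); case-folding; stopword removal; whitespace
collapse. The sequence is iterated to a fixpoint because compatibility
folding can surface new leading digits (e.g. `¼` → `1⁄4`); this guarantees
idempotence, which is property-tested. The stopword list and abbreviation
dictionary are configuration files with French defaults.

**Drug mapping** is a two-hop traversal CIP → ATC → RxNorm; the result
records both hops and the failure mode (`missing first hop` / `missing
second hop`) when incomplete. Unmapped drugs load as concept 0 with the CIP
code preserved in `drug_source_value`.

**Dual annotation and κ.** Level-3 items carry two independent annotator
choices (shipped as a worksheet in `data/mappings.csv`); agreement yields
the consensus directly, disagreement is settled by a third expert and
flagged `adjudicated`. Agreement is quantified with Cohen's unweighted κ
over concept choices, κ = (p_o − p_e)/(1 − p_e), with p_e from the product
of the annotators' marginals. κ is reported on its true range [−1, 1]
(κ = 1 is defined for the degenerate all-one-category case); a brute-force
contingency-table computation serves as the test oracle. Each consensus for
an item with a registered local concept appends a `Maps to` relationship.

**Local concepts** are allocated from a monotonic sequence starting at
2,000,000,001, strictly above every standard concept id; registration is
idempotent on (label, vocabulary, domain). A fuzzy candidate suggester
(normalized edit similarity ≥ 0.85, via difflib) ranks proposals for manual
level-3 work but never auto-accepts.

**Coverage** is reported per (feature, vocabulary): mapped concepts n/N and
mapped records n/N, with percentages rounded to one decimal, half away from
zero (implemented with exact decimal arithmetic). Level-4 rows carry no
fractions.

## Structural mapping

Artificial primary keys come from per-table monotonic sequences; source
identifiers survive only in `*_source_value` columns (pseudonymization is
asserted by scanning every non-source column for source ids). Conventions:

* Visits are single-day (start = end = consultation date), concept
  38004247, one row per consultation with duplicate source ids collapsed.
* MEASUREMENT merges biometrics and laboratory rows; provenance is encoded
  in `measurement_type_concept_id` (EHR physical examination vs Lab 32856)
  rather than a nonstandard extra column, keeping the v5.4 column set.
* Outlier filtering excludes values outside configured per-concept
  plausibility ranges into an itemized rejection log; conservation
  (rows in = rows out + rejections) is exact and tested. Non-numeric values
  where numbers are required are rejections, not aborts.
* Free text (consultation steps, referrals, vaccinations, supplementary
  notes, uncoded histories, external clinical reports) goes to NOTE with a
  class concept per provenance; ICD-10-coded histories go to OBSERVATION;
  syntactically invalid codes load as concept 0 with a conformance flag.
* OBSERVATION_PERIOD is the [min, max] span of each person's dated events
  across visits, measurements, drug exposures, notes and observations;
  persons without dated events get no period.
* Drug exposure end = start + days_supply − 1 when days_supply is present,
  else the start date (a minimal, explicit rule, configurable via
  `EraConfig.exposure_end_rule`).
* DRUG_ERA follows the OHDSI persistence-window convention: exposures are
  resolved to ingredient level (`RxNorm has ingredient`; a concept without
  ingredient links counts as its own ingredient), and per (person,
  ingredient) date-sorted exposures merge while the next start is at most
  `persistence_window` days (default 30) past the running era end.
  `gap_days` accumulates uncovered days between merged exposures — with the
  sort-by-start sweep this equals era span minus covered days, which the
  oracle verifies. The test oracle is an independent pairwise-connectivity
  computation (union-find over the "later start within window of earlier
  end" relation plus a day-set union), compared on 1,000 random instances
  of ≤ 50 exposures for windows {0, 1, 30, 365}.

Structural anomalies the CDM cannot express — laboratory result sets whose
source visit reference does not resolve, invalid ICD-10 codes, exposures
ending before they start — are recorded in a toolkit-specific `etl_audit`
table (outside the OMOP subset, documented as such) that the quality layer
reads; nothing is silently dropped.

## Relational store

The subset comprises 15 OMOP tables (12 clinical/administrative + CONCEPT,
CONCEPT_RELATIONSHIP, VOCABULARY) plus `etl_audit`. The DDL is generated
from a single in-code schema definition and shipped as a versioned SQL file
(a self-check test keeps the two identical). SQLite is the embedded backend
with `PRAGMA foreign_keys = ON`; a pre-load validator mirrors the database
constraints (required columns, PK uniqueness, FK resolution) and itemizes
rejections, and a randomized test confirms validator and database agree
row-for-row. Load order is fixed: vocabulary → administrative → visits →
events → derived tables; loading clinical rows before the vocabulary is an
ordering error.

## Quality assessment

The check registry is declarative (id, Kahn category, description, severity
threshold, runner) so sites can extend it. Defaults: threshold 0 (any
violation fails), post-death grace 0 days, birth years within [1900, 2021],
extraction date 2021-06-30, value ranges per concept from
`data/plausibility.yaml`. Conformance covers key uniqueness, FK closure,
concept-domain and standard-concept discipline, unresolved visit references
and invalid codes; Completeness covers unmapped-concept (id 0) fractions and
missing values; Plausibility covers chronology against birth, death and the
extraction date, value ranges and birth-year bounds. An empty warehouse
passes vacuously. Recall is tested on a closed defect set: each injectable
defect kind fails its corresponding check with an exact violating count, and
a clean build fails nothing.

## The synthetic source generator

The generator *is* the study condition, not a tuning knob. Default rates
are fixed from the volume ratios of a real 20-year primary-care warehouse:
32.2 consultations per patient over the period, 1.56 prescriptions and 0.30
biometric entries per consultation, death rate 0.023, 3.6% of history items
ICD-10-coded, 8 family physicians, observation window 2013-01-01 to
2021-06-30. Laboratory content uses 6 analytes with laboratory-specific
spelling/unit variants (each simulated laboratory consistently uses its
own variant) and plausible normal distributions (e.g. potassium
~ Normal(4.2, 0.4) mmol/L); value draws are clipped into the configured
plausibility ranges so that injected defects are the *only* source of
implausible values — this is what makes the zero-false-alarm quality
property meaningful. Visit counts are Poisson (simplest count model,
parameter-recoverable); free text is template-generated French snippets
with no clinical realism, existing only to be stored in NOTE. Identifiers
are opaque strings; output is byte-identical for identical (config, seed).

The manifest is computed by *rescanning* the generated documents, so
manifest-export consistency holds by construction, including after defect
injection (which mutates copies of the documents and rescans). Defect kinds:
event after death, value out of range, implausible birth year, dangling
visit reference, missing required field (sex).

**What the generator does not emulate:** clinically meaningful narrative
text (so level-4/NLP extraction cannot be exercised), physician-dependent
merging of the four steps into a single field, multi-document patients,
claims/reimbursement data, and realistic correlation structure between
variables. Passing tests therefore demonstrate the correctness of the ETL
machinery on a faithful structural emulation — not mapping coverage or
quality-failure rates of any real site's data, which depend on that site's
vocabularies and habits.

## Validation and dashboard

Five queries (two activity, two prescription, one laboratory — the mix is
enforced) are answered from the warehouse with all events restricted to the
extraction cutoff, and compared with the manifest's source truth; the
end-to-end integration test requires 5/5 exact matches on a defect-free
500-patient export, and raising the cutoff is tested to be monotone.
Mismatches carry a mandatory explanation slot. The dashboard export writes
activity (patients/consultations per physician per year), prescriptions
(exposures per ATC class per year, via the reverse ATC → RxNorm join) and
laboratory distributions (exact order statistics per analyte) as CSV and
JSON; internal-consistency tests tie these totals back to the validation
queries and the DRUG_EXPOSURE row counts.

## Problem sizes and numerical choices

Integration tests run at 30–100 patients; the headline end-to-end and
referential-closure checks run once per session at 500 patients
(≈ 16,000 consultations, ≈ 138,000 loaded rows, about ten seconds), chosen
so the potassium sample (n ≈ 3,500) pins the median within ±0.05 of the
generating mean. Percentages use decimal half-away-from-zero rounding to
one decimal; dates are ISO-8601 calendar dates throughout (the source has
no times); κ returns exact floats with the degenerate p_e = 1 case defined
explicitly.

## Known limitations

* The vocabulary fixture is synthetic (~100 concepts); real OHDSI
  vocabularies are orders of magnitude larger and license-bound, so mapping
  coverage on real data is not represented.
* Level-4 free text is stored, never interpreted; no NLP.
* The embedded backend is SQLite; the DDL is portable SQL but no server
  dialect is exercised in tests.
* DRUG_ERA's `gap_days` counts uncovered days between merged exposures;
  sites using a different bookkeeping convention should treat it as
  informational.
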