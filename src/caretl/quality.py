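"""Kahn-framework data-quality assessment over the loaded CDM.

A declarative registry of verification checks in the three Kahn categories:

* **Conformance** — compliance with relational and formatting definitions:
  key uniqueness, referential integrity, required fields, concept-domain
  agreement, standard-concept discipline, unresolved source references.
* **Completeness** — frequencies of absent attributes: unmapped concepts
  (concept id 0) and missing values.
* **Plausibility** — believability of values: event chronology against
  birth, death and the extraction date, value ranges, birth-year bounds.

Each check compares its violation fraction against a severity threshold
(default 0: any violation fails). The registry is data-driven so sites can
extend it. An empty warehouse passes every check vacuously.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import InputError
from .cdm_transform import PlausibilityRanges

CATEGORIES = ("Conformance", "Completeness", "Plausibility")

_SAMPLE = 10


@dataclass(frozen=True)
class QualityCheck:
    id: str
    category: str
    description: str
    threshold: float
    runner: Callable[[sqlite3.Connection, PlausibilityRanges], tuple[int, int, list]]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise InputError(f"unknown Kahn category {self.category!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise InputError("threshold must lie in [0, 1]")


@dataclass(frozen=True)
class QualityResult:
    check_id: str
    category: str
    description: str
    status: str            # "pass" | "fail"
    violating: int
    total: int
    sample: tuple


def _sql_check(check_id: str, category: str, description: str,
               violation_sql: str, total_sql: str,
               threshold: float = 0.0) -> QualityCheck:
    def runner(conn: sqlite3.Connection, _ranges) -> tuple[int, int, list]:
        keys = [r[0] for r in conn.execute(violation_sql)]
        total = conn.execute(total_sql).fetchone()[0]
        return len(keys), total, keys[:_SAMPLE]
    return QualityCheck(check_id, category, description, threshold, runner)


def _value_range_runner(conn: sqlite3.Connection,
                        ranges: PlausibilityRanges) -> tuple[int, int, list]:
    sample, violating = [], 0
    for concept_id, (lo, hi) in ranges.measurement_ranges.items():
        rows = conn.execute(
            "SELECT measurement_id FROM measurement WHERE measurement_concept_id=? "
            "AND value_as_number IS NOT NULL AND (value_as_number < ? OR "
            "value_as_number > ?)", (concept_id, lo, hi)).fetchall()
        violating += len(rows)
        sample.extend(r[0] for r in rows[:_SAMPLE])
    total = conn.execute("SELECT COUNT(*) FROM measurement").fetchone()[0]
    return violating, total, sample[:_SAMPLE]


def default_registry(ranges: PlausibilityRanges | None = None) -> list[QualityCheck]:
    if ranges is None:
        ranges = PlausibilityRanges.default()
    grace = int(ranges.post_death_grace_days)
    cutoff = ranges.extraction_date
    yob_lo, yob_hi = ranges.birth_year_bounds

    checks = [
        # -- Conformance ----------------------------------------------------
        _sql_check(
            "conf_person_pk_unique", "Conformance",
            "person_id values are unique",
            "SELECT person_id FROM person GROUP BY person_id HAVING COUNT(*) > 1",
            "SELECT COUNT(*) FROM person"),
        _sql_check(
            "conf_visit_person_fk", "Conformance",
            "every visit references an existing person",
            "SELECT visit_occurrence_id FROM visit_occurrence v "
            "WHERE NOT EXISTS (SELECT 1 FROM person p WHERE p.person_id = v.person_id)",
            "SELECT COUNT(*) FROM visit_occurrence"),
        _sql_check(
            "conf_measurement_fk", "Conformance",
            "measurement person/visit foreign keys resolve",
            "SELECT measurement_id FROM measurement m WHERE "
            "NOT EXISTS (SELECT 1 FROM person p WHERE p.person_id = m.person_id) OR "
            "(m.visit_occurrence_id IS NOT NULL AND NOT EXISTS "
            " (SELECT 1 FROM visit_occurrence v "
            "  WHERE v.visit_occurrence_id = m.visit_occurrence_id))",
            "SELECT COUNT(*) FROM measurement"),
        _sql_check(
            "conf_drug_fk", "Conformance",
            "drug exposure person/visit foreign keys resolve",
            "SELECT drug_exposure_id FROM drug_exposure d WHERE "
            "NOT EXISTS (SELECT 1 FROM person p WHERE p.person_id = d.person_id) OR "
            "(d.visit_occurrence_id IS NOT NULL AND NOT EXISTS "
            " (SELECT 1 FROM visit_occurrence v "
            "  WHERE v.visit_occurrence_id = d.visit_occurrence_id))",
            "SELECT COUNT(*) FROM drug_exposure"),
        _sql_check(
            "conf_measurement_domain", "Conformance",
            "mapped measurement concepts belong to the Measurement domain",
            "SELECT measurement_id FROM measurement m JOIN concept c "
            "ON c.concept_id = m.measurement_concept_id "
            "WHERE m.measurement_concept_id != 0 AND c.domain_id != 'Measurement'",
            "SELECT COUNT(*) FROM measurement"),
        _sql_check(
            "conf_drug_domain", "Conformance",
            "mapped drug concepts belong to the Drug domain",
            "SELECT drug_exposure_id FROM drug_exposure d JOIN concept c "
            "ON c.concept_id = d.drug_concept_id "
            "WHERE d.drug_concept_id != 0 AND c.domain_id != 'Drug'",
            "SELECT COUNT(*) FROM drug_exposure"),
        _sql_check(
            "conf_standard_targets", "Conformance",
            "mapped clinical concept ids point at standard concepts",
            "SELECT measurement_id FROM measurement m JOIN concept c "
            "ON c.concept_id = m.measurement_concept_id "
            "WHERE m.measurement_concept_id != 0 AND c.standard_concept != 'S'",
            "SELECT COUNT(*) FROM measurement"),
        _sql_check(
            "conf_unresolved_visit_ref", "Conformance",
            "source visit references all resolved to VISIT_OCCURRENCE rows",
            "SELECT row_id FROM etl_audit WHERE flag = 'unresolved_visit_ref'",
            "SELECT COUNT(*) FROM measurement"),
        _sql_check(
            "conf_invalid_icd10", "Conformance",
            "observation source codes are syntactically valid ICD-10",
            "SELECT row_id FROM etl_audit WHERE flag = 'invalid_icd10'",
            "SELECT COUNT(*) FROM observation"),
        # -- Completeness ---------------------------------------------------
        _sql_check(
            "comp_gender_unknown", "Completeness",
            "persons carry a mapped gender concept",
            "SELECT person_id FROM person WHERE gender_concept_id = 0",
            "SELECT COUNT(*) FROM person"),
        _sql_check(
            "comp_yob_missing", "Completeness",
            "persons carry a year of birth",
            "SELECT person_id FROM person WHERE year_of_birth IS NULL",
            "SELECT COUNT(*) FROM person"),
        _sql_check(
            "comp_measurement_unmapped", "Completeness",
            "measurement labels mapped to a standard concept",
            "SELECT measurement_id FROM measurement WHERE measurement_concept_id = 0",
            "SELECT COUNT(*) FROM measurement"),
        _sql_check(
            "comp_drug_unmapped", "Completeness",
            "drug exposures mapped to a standard concept",
            "SELECT drug_exposure_id FROM drug_exposure WHERE drug_concept_id = 0",
            "SELECT COUNT(*) FROM drug_exposure"),
        _sql_check(
            "comp_observation_unmapped", "Completeness",
            "coded histories mapped to a concept",
            "SELECT observation_id FROM observation WHERE observation_concept_id = 0",
            "SELECT COUNT(*) FROM observation"),
        _sql_check(
            "comp_note_text", "Completeness",
            "notes carry text",
            "SELECT note_id FROM note WHERE note_text IS NULL OR TRIM(note_text) = ''",
            "SELECT COUNT(*) FROM note"),
        # -- Plausibility ---------------------------------------------------
        _sql_check(
            "plaus_visit_after_death", "Plausibility",
            f"no visit after death (+{grace} day grace)",
            "SELECT visit_occurrence_id FROM visit_occurrence v JOIN death d "
            "ON d.person_id = v.person_id "
            f"WHERE v.visit_start_date > date(d.death_date, '+{grace} day')",
            "SELECT COUNT(*) FROM visit_occurrence"),
        _sql_check(
            "plaus_measurement_after_death", "Plausibility",
            f"no measurement after death (+{grace} day grace)",
            "SELECT measurement_id FROM measurement m JOIN death d "
            "ON d.person_id = m.person_id "
            f"WHERE m.measurement_date > date(d.death_date, '+{grace} day')",
            "SELECT COUNT(*) FROM measurement"),
        _sql_check(
            "plaus_visit_before_birth", "Plausibility",
            "no visit before the person's birth year",
            "SELECT visit_occurrence_id FROM visit_occurrence v JOIN person p "
            "ON p.person_id = v.person_id WHERE p.year_of_birth IS NOT NULL "
            "AND CAST(substr(v.visit_start_date, 1, 4) AS INTEGER) < p.year_of_birth",
            "SELECT COUNT(*) FROM visit_occurrence"),
        _sql_check(
            "plaus_event_after_extraction", "Plausibility",
            "no visit after the extraction date",
            "SELECT visit_occurrence_id FROM visit_occurrence "
            f"WHERE visit_start_date > '{cutoff}'",
            "SELECT COUNT(*) FROM visit_occurrence"),
        _sql_check(
            "plaus_birth_year_bounds", "Plausibility",
            f"birth years within [{yob_lo}, {yob_hi}]",
            "SELECT person_id FROM person WHERE year_of_birth IS NOT NULL AND "
            f"(year_of_birth < {yob_lo} OR year_of_birth > {yob_hi})",
            "SELECT COUNT(*) FROM person"),
        _sql_check(
            "plaus_era_chronology", "Plausibility",
            "drug eras end on or after they start",
            "SELECT drug_era_id FROM drug_era "
            "WHERE drug_era_end_date < drug_era_start_date",
            "SELECT COUNT(*) FROM drug_era"),
        QualityCheck(
            "plaus_value_range", "Plausibility",
            "measurement values inside configured plausibility ranges",
            0.0, _value_range_runner),
    ]
    return checks


def run_checks(conn: sqlite3.Connection,
               registry: list[QualityCheck] | None = None,
               ranges: PlausibilityRanges | None = None) -> list[QualityResult]:
    """Execute the full registry; fail ⇔ violation fraction > threshold."""
    if ranges is None:
        ranges = PlausibilityRanges.default()
    if registry is None:
        registry = default_registry(ranges)
    results = []
    for check in registry:
        violating, total, sample = check.runner(conn, ranges)
        fraction = (violating / total) if total else 0.0
        results.append(QualityResult(
            check.id, check.category, check.description,
            "fail" if fraction > check.threshold else "pass",
            violating, total, tuple(sample)))
    return results


def summarize_checks(results: list[QualityResult]) -> dict[str, dict[str, int]]:
    """Pass/fail counts per Kahn category; counts partition the results."""
    if not results:
        raise InputError("summarize_checks requires at least one result")
    summary = {c: {"pass": 0, "fail": 0} for c in CATEGORIES}
    for r in results:
        summary[r.category][r.status] += 1
    return summary


@dataclass(frozen=True)
class DistributionSummary:
    concept_id: int
    n: int
    minimum: float
    p25: float
    median: float
    p75: float
    maximum: float
    out_of_range: int


def value_distribution(conn: sqlite3.Connection, concept_id: int,
                       ranges: PlausibilityRanges | None = None) -> DistributionSummary:
    """Exact order statistics of the stored values for one measurement
    concept, with the count of values outside its plausibility range."""
    values = np.array([r[0] for r in conn.execute(
        "SELECT value_as_number FROM measurement WHERE measurement_concept_id = ? "
        "AND value_as_number IS NOT NULL", (concept_id,))])
    if values.size == 0:
        raise LookupError(f"no measurement values for concept {concept_id}")
    if ranges is None:
        ranges = PlausibilityRanges.default()
    bounds = ranges.measurement_ranges.get(concept_id)
    out = int(((values < bounds[0]) | (values > bounds[1])).sum()) if bounds else 0
    return DistributionSummary(
        concept_id, int(values.size), float(values.min()),
        float(np.percentile(values, 25)), float(np.median(values)),
        float(np.percentile(values, 75)), float(values.max()), out)
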