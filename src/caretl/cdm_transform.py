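"""Structural mapping: staging entities + mapping ledger → OMOP CDM v5.4 rows.

Every clinical row carries a dense, freshly sequenced artificial primary key
(pseudonymization: source identifiers survive only in ``*_source_value``
columns), a standard ``x_concept_id`` (0 when unmapped, per OMOP
convention), and a type concept identifying provenance. Consultations become
single-day ambulatory visits (visit_concept_id 38004247); biometric and
laboratory rows share the MEASUREMENT table and are distinguished by their
measurement type concept (EHR physical examination vs Lab, 32856); free text
goes to NOTE; ICD-10-coded histories go to OBSERVATION.

Two derived tables are computed: OBSERVATION_PERIOD as the [min, max] span
of each person's dated events (persons without events get no period) and
DRUG_ERA by the standard OHDSI convention — exposures resolved to ingredient
level and merged per (person, ingredient) whenever the gap to the next
exposure is at most the persistence window (default 30 days).

Rows the transform cannot express as valid CDM content are never silently
dropped: out-of-range or non-numeric measurement values go to a rejection
log, and structural anomalies (unresolved visit references, invalid ICD-10
codes, exposures ending before they start) are recorded in the toolkit's
``etl_audit`` side table, which the quality layer reads.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError, IntegrityError
from .extract import StagingStore
from .vocabulary import ConceptStore, MappingLedger, map_drug

_DATA_DIR = Path(__file__).parent / "data"

VISIT_CONCEPT_ID = 38004247        # Ambulatory Primary Care Clinic/Center
TYPE_EHR = 32817
TYPE_LAB = 32856
TYPE_PHYSICAL_EXAM = 44818701
TYPE_EHR_PRESCRIPTION = 32838

NOTE_CLASS_CONCEPTS = {
    "reason": 45900001,
    "interview": 45900002,
    "diagnosis": 45900003,
    "referral": 45900004,
    "vaccination": 45900005,
    "history": 45900006,
    "clinical_report": 45900007,
    "supplementary": 45900008,
}

_ICD10_SYNTAX = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")


class IdSequence:
    """Strictly monotonic artificial-identifier sequence for one CDM table."""

    def __init__(self, name: str, start: int = 1):
        self.name = name
        self._next = start

    def next(self) -> int:
        value = self._next
        self._next += 1
        return value

    @property
    def current(self) -> int:
        return self._next


def make_sequences() -> dict[str, IdSequence]:
    names = ("person", "location", "provider", "care_site", "visit_occurrence",
             "measurement", "drug_exposure", "drug_era", "note", "observation",
             "observation_period", "etl_audit")
    return {n: IdSequence(n) for n in names}


@dataclass(frozen=True)
class EraConfig:
    """Drug-era derivation parameters (OHDSI persistence-window convention)."""

    persistence_window: int = 30
    exposure_end_rule: str = "start_plus_days_supply"  # or "start_only"

    def __post_init__(self):
        if self.persistence_window < 0:
            raise ConfigurationError("persistence_window must be >= 0")
        if self.exposure_end_rule not in ("start_plus_days_supply", "start_only"):
            raise ConfigurationError(f"unknown exposure_end_rule {self.exposure_end_rule!r}")


@dataclass
class PlausibilityRanges:
    """Configured plausibility bounds used by the outlier filter and the
    quality layer."""

    measurement_ranges: dict[int, tuple[float, float]]
    birth_year_bounds: tuple[int, int] = (1900, 2021)
    post_death_grace_days: int = 0
    extraction_date: str = "2021-06-30"

    def __post_init__(self):
        for cid, (lo, hi) in self.measurement_ranges.items():
            if lo >= hi:
                raise ConfigurationError(f"range for concept {cid} has min >= max")

    @classmethod
    def default(cls) -> "PlausibilityRanges":
        with open(_DATA_DIR / "plausibility.yaml", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            measurement_ranges={int(m["concept_id"]): (float(m["min"]), float(m["max"]))
                                for m in cfg["measurements"]},
            birth_year_bounds=(int(cfg["birth_year"]["min"]), int(cfg["birth_year"]["max"])),
            post_death_grace_days=int(cfg["post_death_grace_days"]),
            extraction_date=str(cfg["extraction_date"]),
        )


@dataclass
class CdmTables:
    """The transformed warehouse content, one DataFrame per target table."""

    tables: dict[str, pd.DataFrame]
    measurement_rejects: list[dict] = field(default_factory=list)
    drug_rejects: list[dict] = field(default_factory=list)
    note_skips: list[dict] = field(default_factory=list)

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]


def _consensus(ledger: MappingLedger, feature: str, raw) -> tuple[int, int]:
    """(standard concept id, source concept id) for a raw label, 0 if unmapped."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return 0, 0
    item = ledger.lookup(feature, str(raw))
    if item is None:
        return 0, 0
    std = item.consensus if item.consensus is not None else 0
    src = (item.local_concept_id if item.local_concept_id is not None
           else item.source_concept_id if item.source_concept_id is not None else 0)
    return std, src


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_demographics(staging: StagingStore, ledger: MappingLedger,
                       seqs: dict[str, IdSequence]) -> dict:
    """PERSON, LOCATION (deduplicated), PROVIDER, one CARE_SITE, DEATH."""
    if staging.patients.empty:
        raise IntegrityError("staging contains no patients")

    care_site_id = seqs["care_site"].next()
    care_site = pd.DataFrame([{
        "care_site_id": care_site_id,
        "care_site_name": "Multidisciplinary health center",
        "place_of_service_concept_id": VISIT_CONCEPT_ID,
        "care_site_source_value": "MHC",
    }])

    provider_rows, provider_ids = [], {}
    for phys in staging.providers["physician"]:
        pid = seqs["provider"].next()
        provider_ids[phys] = pid
        provider_rows.append({"provider_id": pid, "provider_name": phys,
                              "care_site_id": care_site_id, "provider_source_value": phys})
    provider = pd.DataFrame(provider_rows,
                            columns=["provider_id", "provider_name", "care_site_id",
                                     "provider_source_value"])

    location_rows, location_ids = [], {}
    for row in staging.addresses.itertuples(index=False):
        key = (row.line, row.town, row.zip)
        if key in location_ids:
            continue
        lid = seqs["location"].next()
        location_ids[key] = lid
        location_rows.append({"location_id": lid, "city": row.town, "zip": row.zip,
                              "location_source_value": row.line})
    location = pd.DataFrame(location_rows,
                            columns=["location_id", "city", "zip", "location_source_value"])

    patient_location = {}
    for row in staging.addresses.itertuples(index=False):
        patient_location.setdefault(row.patient_id,
                                    location_ids[(row.line, row.town, row.zip)])

    person_rows, person_ids = [], {}
    for row in staging.patients.itertuples(index=False):
        pid = seqs["person"].next()
        person_ids[row.patient_id] = pid
        gender_id, _ = _consensus(ledger, "sex", row.sex)
        try:
            yob = int(row.year_of_birth)
        except (TypeError, ValueError):
            yob = None
        person_rows.append({
            "person_id": pid,
            "gender_concept_id": gender_id,
            "year_of_birth": yob,
            "race_concept_id": 0,
            "ethnicity_concept_id": 0,
            "location_id": patient_location.get(row.patient_id),
            "provider_id": provider_ids.get(row.physician),
            "care_site_id": care_site_id,
            "person_source_value": row.patient_id,
            "gender_source_value": row.sex,
        })
    person = pd.DataFrame(person_rows)

    death_rows = []
    for row in staging.deaths.itertuples(index=False):
        death_rows.append({"person_id": person_ids[row.patient_id],
                           "death_date": row.death_date,
                           "death_type_concept_id": TYPE_EHR})
    death = pd.DataFrame(death_rows,
                         columns=["person_id", "death_date", "death_type_concept_id"])

    return {"person": person, "location": location, "provider": provider,
            "care_site": care_site, "death": death,
            "person_ids": person_ids, "provider_ids": provider_ids}


def build_visits(consultations: pd.DataFrame, person_ids: dict[str, int],
                 seqs: dict[str, IdSequence],
                 provider_of_person: dict[int, int] | None = None,
                 care_site_id: int | None = None) -> tuple[pd.DataFrame, dict[str, int]]:
    """One single-day VISIT_OCCURRENCE row per consultation.

    Duplicate source consultation identifiers collapse to one row; a
    consultation referencing an unknown patient is an integrity error.
    """
    rows, visit_ids = [], {}
    for row in consultations.itertuples(index=False):
        if row.patient_id not in person_ids:
            raise IntegrityError(
                f"consultation {row.consultation_id} references unknown patient "
                f"{row.patient_id}")
        if row.consultation_id in visit_ids:
            continue  # duplicated source row collapses
        vid = seqs["visit_occurrence"].next()
        visit_ids[row.consultation_id] = vid
        person_id = person_ids[row.patient_id]
        rows.append({
            "visit_occurrence_id": vid,
            "person_id": person_id,
            "visit_concept_id": VISIT_CONCEPT_ID,
            "visit_start_date": row.date,
            "visit_end_date": row.date,
            "visit_type_concept_id": TYPE_EHR,
            "provider_id": (provider_of_person or {}).get(person_id),
            "care_site_id": care_site_id,
            "visit_source_value": row.consultation_id,
        })
    columns = ["visit_occurrence_id", "person_id", "visit_concept_id",
               "visit_start_date", "visit_end_date", "visit_type_concept_id",
               "provider_id", "care_site_id", "visit_source_value"]
    return pd.DataFrame(rows, columns=columns), visit_ids


def build_measurements(biometrics: pd.DataFrame, lab_results: pd.DataFrame,
                       ledger: MappingLedger, ranges: PlausibilityRanges | None,
                       person_ids: dict[str, int], visit_ids: dict[str, int],
                       seqs: dict[str, IdSequence],
                       filter_outliers: bool = True) -> tuple[pd.DataFrame, list[dict], list[dict]]:
    """MEASUREMENT rows from the biometrics and laboratory staging tables.

    Returns (rows, rejection log, audit flags). Conservation holds exactly:
    input rows = emitted rows + rejection-log entries.
    """
    rows: list[dict] = []
    rejects: list[dict] = []
    audit: list[dict] = []

    def emit(source: str, feature: str, type_concept: int, row, visit_id,
             visit_ref_unresolved: bool):
        concept_id, source_concept_id = _consensus(ledger, feature, row.variable)
        unit_id, _ = _consensus(ledger, "unit", row.unit)
        try:
            value = float(row.value)
        except (TypeError, ValueError):
            rejects.append({"source": source, "patient_id": row.patient_id,
                            "variable": row.variable, "value": row.value,
                            "reason": "non-numeric value"})
            return
        if filter_outliers and ranges is not None:
            bounds = ranges.measurement_ranges.get(concept_id)
            if bounds and not bounds[0] <= value <= bounds[1]:
                rejects.append({"source": source, "patient_id": row.patient_id,
                                "variable": row.variable, "value": value,
                                "reason": f"out of range {list(bounds)}"})
                return
        mid = seqs["measurement"].next()
        rows.append({
            "measurement_id": mid,
            "person_id": person_ids[row.patient_id],
            "measurement_concept_id": concept_id,
            "measurement_date": row.date,
            "measurement_type_concept_id": type_concept,
            "value_as_number": value,
            "unit_concept_id": unit_id,
            "visit_occurrence_id": visit_id,
            "measurement_source_value": row.variable,
            "measurement_source_concept_id": source_concept_id,
            "unit_source_value": row.unit,
        })
        if visit_ref_unresolved:
            audit.append({"table_name": "measurement", "row_id": mid,
                          "flag": "unresolved_visit_ref",
                          "detail": f"source visit reference {row.consultation_ref!r} "
                                    "does not resolve"})

    for row in biometrics.itertuples(index=False):
        emit("biometrics", "biometric", TYPE_PHYSICAL_EXAM, row,
             visit_ids.get(row.consultation_id), False)
    for row in lab_results.itertuples(index=False):
        ref = row.consultation_ref
        has_ref = ref is not None and not (isinstance(ref, float) and pd.isna(ref))
        visit_id = visit_ids.get(ref) if has_ref else None
        emit("laboratory", "laboratory", TYPE_LAB, row, visit_id,
             has_ref and visit_id is None)

    columns = ["measurement_id", "person_id", "measurement_concept_id",
               "measurement_date", "measurement_type_concept_id", "value_as_number",
               "unit_concept_id", "visit_occurrence_id", "measurement_source_value",
               "measurement_source_concept_id", "unit_source_value"]
    return pd.DataFrame(rows, columns=columns), rejects, audit


def build_drug_exposures(prescriptions: pd.DataFrame, store: ConceptStore,
                         person_ids: dict[str, int], visit_ids: dict[str, int],
                         seqs: dict[str, IdSequence],
                         era_config: EraConfig = EraConfig()) -> tuple[pd.DataFrame, list[dict]]:
    """DRUG_EXPOSURE rows, one per prescription, with the two-hop RxNorm
    mapping applied (concept 0 and the raw CIP preserved when unmappable)."""
    rows, rejects = [], []
    cache: dict[str, tuple[int, int]] = {}
    for row in prescriptions.itertuples(index=False):
        cip = row.cip_code
        if cip not in cache:
            try:
                m = map_drug(cip, store)
                cache[cip] = (m.rxnorm_concept_id or 0, m.cip_concept_id or 0)
            except Exception:
                cache[cip] = (0, 0)
        concept_id, source_concept_id = cache[cip]
        try:
            days_supply = int(row.days_supply)
        except (TypeError, ValueError):
            days_supply = None
        start = row.date
        if start is None or (isinstance(start, float) and pd.isna(start)):
            rejects.append({"patient_id": row.patient_id, "cip": cip,
                            "reason": "missing start date"})
            continue
        if era_config.exposure_end_rule == "start_plus_days_supply" and days_supply:
            end = (dt.date.fromisoformat(start)
                   + dt.timedelta(days=days_supply - 1)).isoformat()
        else:
            end = start
        rows.append({
            "drug_exposure_id": seqs["drug_exposure"].next(),
            "person_id": person_ids[row.patient_id],
            "drug_concept_id": concept_id,
            "drug_exposure_start_date": start,
            "drug_exposure_end_date": end,
            "drug_type_concept_id": TYPE_EHR_PRESCRIPTION,
            "quantity": _maybe_int(row.quantity),
            "days_supply": days_supply,
            "refills": _maybe_int(row.refills),
            "visit_occurrence_id": visit_ids.get(row.consultation_id),
            "drug_source_value": cip,
            "drug_source_concept_id": source_concept_id,
        })
    columns = ["drug_exposure_id", "person_id", "drug_concept_id",
               "drug_exposure_start_date", "drug_exposure_end_date",
               "drug_type_concept_id", "quantity", "days_supply", "refills",
               "visit_occurrence_id", "drug_source_value", "drug_source_concept_id"]
    return pd.DataFrame(rows, columns=columns), rejects


def _maybe_int(value):
    try:
        return int(value)
    except (TypeError, ValueError):
        return None


def build_notes(free_text_items: pd.DataFrame, person_ids: dict[str, int],
                visit_ids: dict[str, int],
                seqs: dict[str, IdSequence]) -> tuple[pd.DataFrame, list[dict]]:
    """One NOTE row per free-text item, class concept encoding provenance.

    ``free_text_items`` needs columns patient_id, consultation_id, date,
    provenance, text. Empty texts are skipped with a log entry.
    """
    rows, skips = [], []
    for row in free_text_items.itertuples(index=False):
        if row.text is None or str(row.text).strip() == "" or pd.isna(row.text):
            skips.append({"patient_id": row.patient_id, "provenance": row.provenance,
                          "reason": "empty text"})
            continue
        rows.append({
            "note_id": seqs["note"].next(),
            "person_id": person_ids[row.patient_id],
            "note_date": row.date,
            "note_type_concept_id": TYPE_EHR,
            "note_class_concept_id": NOTE_CLASS_CONCEPTS.get(row.provenance, 0),
            "note_title": row.provenance,
            "note_text": row.text,
            "encoding_concept_id": 0,
            "language_concept_id": 0,
            "visit_occurrence_id": visit_ids.get(row.consultation_id),
            "note_source_value": row.provenance,
        })
    columns = ["note_id", "person_id", "note_date", "note_type_concept_id",
               "note_class_concept_id", "note_title", "note_text",
               "encoding_concept_id", "language_concept_id", "visit_occurrence_id",
               "note_source_value"]
    return pd.DataFrame(rows, columns=columns), skips


def assemble_free_text_items(staging: StagingStore) -> pd.DataFrame:
    """Free-text items destined for NOTE: the staged notes plus the
    free-text (uncoded) medical histories."""
    free_hist = staging.histories[~staging.histories["coded"]]
    hist_items = pd.DataFrame({
        "patient_id": free_hist["patient_id"],
        "consultation_id": None,
        "date": free_hist["date"],
        "provenance": "history",
        "text": free_hist["text"],
    })
    return pd.concat([staging.notes, hist_items], ignore_index=True)


def build_observations(histories: pd.DataFrame, ledger: MappingLedger,
                       person_ids: dict[str, int],
                       seqs: dict[str, IdSequence]) -> tuple[pd.DataFrame, list[dict]]:
    """OBSERVATION rows for ICD-10-coded histories only (free text is routed
    to NOTE). Syntactically invalid codes yield concept 0 plus a conformance
    audit flag."""
    rows, audit = [], []
    coded = histories[histories["coded"]]
    for row in coded.itertuples(index=False):
        code = row.code
        oid = seqs["observation"].next()
        concept_id, source_concept_id = _consensus(ledger, "medical_history", code)
        if code is None or not _ICD10_SYNTAX.match(str(code)):
            concept_id, source_concept_id = 0, 0
            audit.append({"table_name": "observation", "row_id": oid,
                          "flag": "invalid_icd10",
                          "detail": f"syntactically invalid ICD-10 code {code!r}"})
        rows.append({
            "observation_id": oid,
            "person_id": person_ids[row.patient_id],
            "observation_concept_id": concept_id,
            "observation_date": row.date,
            "observation_type_concept_id": TYPE_EHR,
            "value_as_string": None,
            "visit_occurrence_id": None,
            "observation_source_value": code,
            "observation_source_concept_id": source_concept_id,
        })
    columns = ["observation_id", "person_id", "observation_concept_id",
               "observation_date", "observation_type_concept_id", "value_as_string",
               "visit_occurrence_id", "observation_source_value",
               "observation_source_concept_id"]
    return pd.DataFrame(rows, columns=columns), audit


def derive_observation_periods(event_frames: list[tuple[pd.DataFrame, str]],
                               seqs: dict[str, IdSequence]) -> pd.DataFrame:
    """At most one OBSERVATION_PERIOD per person: [earliest, latest] dated
    event across the clinical tables. Persons with no dated events get none."""
    extents: dict[int, tuple[str, str]] = {}
    for frame, date_col in event_frames:
        if frame.empty:
            continue
        sub = frame[["person_id", date_col]].dropna()
        for person_id, date in sub.itertuples(index=False):
            cur = extents.get(person_id)
            if cur is None:
                extents[person_id] = (date, date)
            else:
                extents[person_id] = (min(cur[0], date), max(cur[1], date))
    rows = [{
        "observation_period_id": seqs["observation_period"].next(),
        "person_id": person_id,
        "observation_period_start_date": lo,
        "observation_period_end_date": hi,
        "period_type_concept_id": TYPE_EHR,
    } for person_id, (lo, hi) in sorted(extents.items())]
    columns = ["observation_period_id", "person_id", "observation_period_start_date",
               "observation_period_end_date", "period_type_concept_id"]
    return pd.DataFrame(rows, columns=columns)


def resolve_ingredients(concept_id: int, store: ConceptStore) -> list[int]:
    """Ingredient concepts of a drug concept; a concept with no
    has-ingredient links is taken to be an ingredient itself."""
    if concept_id == 0:
        return []
    ingredients = store.related(concept_id, "RxNorm has ingredient")
    return sorted(ingredients) if ingredients else [concept_id]


def derive_drug_eras(exposures: pd.DataFrame, store: ConceptStore,
                     cfg: EraConfig, seqs: dict[str, IdSequence]) -> tuple[pd.DataFrame, list[dict]]:
    """DRUG_ERA via the persistence-window convention.

    Exposures are resolved to ingredient level (a combination product yields
    one era stream per ingredient, so eras can outnumber exposures); per
    (person, ingredient) the date-sorted exposures merge while the next
    start is at most ``persistence_window`` days after the running era end.
    ``gap_days`` accumulates the uncovered days between merged exposures.
    Exposures ending before they start are excluded and audit-flagged.
    """
    audit: list[dict] = []
    streams: dict[tuple[int, int], list[tuple[dt.date, dt.date]]] = {}
    for row in exposures.itertuples(index=False):
        start = dt.date.fromisoformat(row.drug_exposure_start_date)
        end = dt.date.fromisoformat(row.drug_exposure_end_date)
        if end < start:
            audit.append({"table_name": "drug_exposure", "row_id": row.drug_exposure_id,
                          "flag": "exposure_end_before_start",
                          "detail": f"{end} < {start}"})
            continue
        for ingredient in resolve_ingredients(row.drug_concept_id, store):
            streams.setdefault((row.person_id, ingredient), []).append((start, end))

    rows = []
    for (person_id, ingredient), spans in sorted(streams.items()):
        spans.sort()
        era_start, era_end = spans[0]
        count, gap_days = 1, 0
        for start, end in spans[1:]:
            if (start - era_end).days <= cfg.persistence_window:
                gap_days += max(0, (start - era_end).days - 1)
                era_end = max(era_end, end)
                count += 1
            else:
                rows.append((person_id, ingredient, era_start, era_end, count, gap_days))
                era_start, era_end, count, gap_days = start, end, 1, 0
        rows.append((person_id, ingredient, era_start, era_end, count, gap_days))

    records = [{
        "drug_era_id": seqs["drug_era"].next(),
        "person_id": person_id,
        "drug_concept_id": ingredient,
        "drug_era_start_date": start.isoformat(),
        "drug_era_end_date": end.isoformat(),
        "drug_exposure_count": count,
        "gap_days": gap_days,
    } for person_id, ingredient, start, end, count, gap_days in rows]
    columns = ["drug_era_id", "person_id", "drug_concept_id", "drug_era_start_date",
               "drug_era_end_date", "drug_exposure_count", "gap_days"]
    return pd.DataFrame(records, columns=columns), audit


# ---------------------------------------------------------------------------
# full build
# ---------------------------------------------------------------------------

def build_cdm(staging: StagingStore, ledger: MappingLedger, store: ConceptStore,
              ranges: PlausibilityRanges | None = None,
              era_config: EraConfig = EraConfig(),
              filter_outliers: bool = True) -> CdmTables:
    """Run the whole structural mapping and derivation pipeline."""
    seqs = make_sequences()
    audit_rows: list[dict] = []

    demo = build_demographics(staging, ledger, seqs)
    provider_of_person = {
        row.person_id: row.provider_id
        for row in demo["person"].itertuples(index=False) if row.provider_id}
    visit, visit_ids = build_visits(
        staging.consultations, demo["person_ids"], seqs,
        provider_of_person, int(demo["care_site"]["care_site_id"].iloc[0]))
    measurement, meas_rejects, meas_audit = build_measurements(
        staging.biometrics, staging.lab_results, ledger, ranges,
        demo["person_ids"], visit_ids, seqs, filter_outliers)
    audit_rows.extend(meas_audit)
    drug_exposure, drug_rejects = build_drug_exposures(
        staging.prescriptions, store, demo["person_ids"], visit_ids, seqs)
    note, note_skips = build_notes(assemble_free_text_items(staging),
                                   demo["person_ids"], visit_ids, seqs)
    observation, obs_audit = build_observations(staging.histories, ledger,
                                                demo["person_ids"], seqs)
    audit_rows.extend(obs_audit)
    observation_period = derive_observation_periods(
        [(visit, "visit_start_date"), (measurement, "measurement_date"),
         (drug_exposure, "drug_exposure_start_date"), (note, "note_date"),
         (observation, "observation_date")], seqs)
    drug_era, era_audit = derive_drug_eras(drug_exposure, store, era_config, seqs)
    audit_rows.extend(era_audit)

    audit = pd.DataFrame(
        [{"audit_id": seqs["etl_audit"].next(), **row} for row in audit_rows],
        columns=["audit_id", "table_name", "row_id", "flag", "detail"])

    tables = {
        "person": demo["person"], "location": demo["location"],
        "provider": demo["provider"], "care_site": demo["care_site"],
        "death": demo["death"], "visit_occurrence": visit,
        "measurement": measurement, "drug_exposure": drug_exposure,
        "drug_era": drug_era, "note": note, "observation": observation,
        "observation_period": observation_period, "etl_audit": audit,
    }
    return CdmTables(tables, meas_rejects, drug_rejects, note_skips)
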