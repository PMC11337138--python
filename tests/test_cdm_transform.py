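"""Structural mapping: builders, derived tables, conservation, era oracle."""

import numpy as np
import pandas as pd
import pytest

from caretl import (Concept, ConceptStore, EraConfig, MappingItem, MappingLedger,
                    PlausibilityRanges, bundled_store, build_cdm, build_ledger,
                    extract_all)
from caretl.cdm_transform import (build_demographics, build_drug_exposures,
                                  build_measurements, build_notes,
                                  build_observations, build_visits,
                                  derive_drug_eras, derive_observation_periods,
                                  make_sequences, NOTE_CLASS_CONCEPTS,
                                  TYPE_LAB, TYPE_PHYSICAL_EXAM, VISIT_CONCEPT_ID)
from caretl.errors import IntegrityError
from caretl.extract import StagingStore, STAGING_TABLES, _COLUMNS


def make_staging(**overrides) -> StagingStore:
    frames = {t: pd.DataFrame(columns=_COLUMNS[t]) for t in STAGING_TABLES}
    for name, rows in overrides.items():
        frames[name] = pd.DataFrame(rows, columns=_COLUMNS[name])
    return StagingStore(**frames)


def sex_ledger() -> MappingLedger:
    ledger = MappingLedger()
    ledger.add(MappingItem("sex", "M", "m", "local", "Gender", 3, consensus=8507))
    ledger.add(MappingItem("sex", "F", "f", "local", "Gender", 3, consensus=8532))
    return ledger


# -- demographics ------------------------------------------------------------

def test_demographics_location_dedup_and_death():
    staging = make_staging(
        patients=[{"patient_id": "A", "sex": "F", "year_of_birth": "1970",
                   "physician": "dr-01"},
                  {"patient_id": "B", "sex": "M", "year_of_birth": "1980",
                   "physician": "dr-01"},
                  {"patient_id": "C", "sex": "F", "year_of_birth": "1990",
                   "physician": "dr-02"}],
        addresses=[{"patient_id": "A", "line": "1 rue X", "town": "Lille", "zip": "59"},
                   {"patient_id": "B", "line": "1 rue X", "town": "Lille", "zip": "59"},
                   {"patient_id": "C", "line": "2 rue Y", "town": "Lille", "zip": "59"}],
        providers=[{"physician": "dr-01"}, {"physician": "dr-02"}],
        deaths=[{"patient_id": "B", "death_date": "2020-01-01"}])
    demo = build_demographics(staging, sex_ledger(), make_sequences())
    assert len(demo["person"]) == 3
    assert len(demo["location"]) == 2          # shared address deduplicated
    assert len(demo["care_site"]) == 1
    assert list(demo["person"]["person_id"]) == [1, 2, 3]
    assert set(demo["person"]["gender_concept_id"]) == {8507, 8532}
    death = demo["death"]
    assert len(death) == 1
    assert death["person_id"].iloc[0] == demo["person_ids"]["B"]


def test_unmapped_sex_becomes_concept_zero():
    staging = make_staging(patients=[{"patient_id": "A", "sex": "X",
                                      "year_of_birth": "1970"}])
    demo = build_demographics(staging, sex_ledger(), make_sequences())
    assert demo["person"]["gender_concept_id"].iloc[0] == 0
    assert demo["person"]["gender_source_value"].iloc[0] == "X"


# -- visits ------------------------------------------------------------------

def test_visits_one_row_per_consultation_and_dedup():
    consultations = pd.DataFrame([
        {"patient_id": "A", "consultation_id": f"c{i}", "date": "2019-01-01"}
        for i in range(3)] + [
        {"patient_id": "B", "consultation_id": "c3", "date": "2019-02-01"},
        {"patient_id": "B", "consultation_id": "c4", "date": "2019-02-02"},
        {"patient_id": "B", "consultation_id": "c4", "date": "2019-02-02"},  # dup
    ])
    visits, visit_ids = build_visits(consultations, {"A": 1, "B": 2},
                                     make_sequences())
    assert len(visits) == 5                    # 6 source rows, 1 duplicate
    assert (visits["visit_concept_id"] == VISIT_CONCEPT_ID).all()
    assert (visits["visit_start_date"] == visits["visit_end_date"]).all()


def test_visit_unknown_patient_is_integrity_error():
    consultations = pd.DataFrame([{"patient_id": "ghost", "consultation_id": "c1",
                                   "date": "2019-01-01"}])
    with pytest.raises(IntegrityError, match="ghost"):
        build_visits(consultations, {"A": 1}, make_sequences())


# -- measurements ------------------------------------------------------------

def lab_ledger() -> MappingLedger:
    ledger = MappingLedger()
    ledger.add(MappingItem("laboratory", "Potassium", "potassium", "local", "LOINC",
                           3, consensus=45200002, local_concept_id=2000000001))
    ledger.add(MappingItem("unit", "mmol/L", "mmol l", "local", "UCUM", 3,
                           consensus=45400005))
    return ledger


def _lab_row(value, ref=None):
    return {"patient_id": "A", "result_set_id": "rs", "laboratory": "lab-1",
            "date": "2019-05-01", "consultation_ref": ref,
            "variable": "Potassium", "value": value, "unit": "mmol/L"}


def test_measurement_range_filter_and_conservation():
    ranges = PlausibilityRanges({45200002: (1.5, 8.0)})
    labs = pd.DataFrame([_lab_row("4.1"), _lab_row("410"), _lab_row("oops")])
    rows, rejects, audit = build_measurements(
        pd.DataFrame(columns=_COLUMNS["biometrics"]), labs, lab_ledger(), ranges,
        {"A": 1}, {}, make_sequences())
    assert len(rows) == 1 and len(rejects) == 2
    assert rows["value_as_number"].iloc[0] == 4.1
    assert rows["measurement_type_concept_id"].iloc[0] == TYPE_LAB
    assert rows["measurement_source_concept_id"].iloc[0] == 2000000001
    reasons = {r["reason"] for r in rejects}
    assert any("out of range" in r for r in reasons)
    assert any("non-numeric" in r for r in reasons)


def test_measurement_unmapped_label_kept_with_concept_zero():
    labs = pd.DataFrame([dict(_lab_row("1.0"), variable="mystery")])
    rows, rejects, _ = build_measurements(
        pd.DataFrame(columns=_COLUMNS["biometrics"]), labs, lab_ledger(), None,
        {"A": 1}, {}, make_sequences())
    assert len(rows) == 1 and not rejects
    assert rows["measurement_concept_id"].iloc[0] == 0
    assert rows["measurement_source_value"].iloc[0] == "mystery"


def test_measurement_unresolved_visit_ref_flagged():
    labs = pd.DataFrame([_lab_row("4.0", ref="missing-c1")])
    rows, _rejects, audit = build_measurements(
        pd.DataFrame(columns=_COLUMNS["biometrics"]), labs, lab_ledger(), None,
        {"A": 1}, {"c-real": 7}, make_sequences())
    assert rows["visit_occurrence_id"].isna().all()
    assert len(audit) == 1 and audit[0]["flag"] == "unresolved_visit_ref"


def test_biometric_rows_typed_physical_exam(clean_pipeline):
    m = clean_pipeline.cdm["measurement"]
    types = set(m["measurement_type_concept_id"])
    assert types == {TYPE_LAB, TYPE_PHYSICAL_EXAM}


# -- drug exposures ----------------------------------------------------------

def test_drug_exposure_mapping_and_source_preservation():
    store = bundled_store()
    known = next(c.concept_code for c in store.concepts if c.vocabulary_id == "CIP")
    rx = pd.DataFrame([
        {"patient_id": "A", "consultation_id": "c1", "date": "2019-01-01",
         "cip_code": known, "days_supply": "30", "quantity": "1", "refills": "0"},
        {"patient_id": "A", "consultation_id": "c1", "date": "2019-01-01",
         "cip_code": "9999999999999", "days_supply": None, "quantity": None,
         "refills": None}])
    rows, rejects = build_drug_exposures(rx, store, {"A": 1}, {"c1": 5},
                                         make_sequences())
    assert len(rows) == 2 and not rejects
    mapped = rows[rows["drug_source_value"] == known].iloc[0]
    assert mapped["drug_concept_id"] != 0
    assert mapped["drug_exposure_end_date"] == "2019-01-30"  # start + 30 − 1
    unmapped = rows[rows["drug_source_value"] == "9999999999999"].iloc[0]
    assert unmapped["drug_concept_id"] == 0
    assert unmapped["drug_exposure_end_date"] == "2019-01-01"


# -- notes and observations --------------------------------------------------

def test_notes_distinct_provenance_concepts_and_empty_skip():
    items = pd.DataFrame([
        {"patient_id": "A", "consultation_id": "c1", "date": "2019-01-01",
         "provenance": p, "text": f"text {p}"}
        for p in ("reason", "interview", "diagnosis")] + [
        {"patient_id": "A", "consultation_id": "c1", "date": "2019-01-01",
         "provenance": "reason", "text": "  "}])
    rows, skips = build_notes(items, {"A": 1}, {"c1": 9}, make_sequences())
    assert len(rows) == 3 and len(skips) == 1
    assert rows["note_class_concept_id"].nunique() == 3
    assert set(rows["note_class_concept_id"]) == {
        NOTE_CLASS_CONCEPTS["reason"], NOTE_CLASS_CONCEPTS["interview"],
        NOTE_CLASS_CONCEPTS["diagnosis"]}


def test_free_text_history_routed_to_note_not_observation(small_export):
    export, _ = small_export
    staging = extract_all(export)
    store = bundled_store()
    ledger, _ = build_ledger(staging, store)
    cdm = build_cdm(staging, ledger, store)
    n_coded = int(staging.histories["coded"].sum())
    n_free = len(staging.histories) - n_coded
    assert len(cdm["observation"]) == n_coded
    assert (cdm["note"]["note_source_value"] == "history").sum() == n_free


def test_invalid_icd10_flagged():
    histories = pd.DataFrame([
        {"patient_id": "A", "coded": True, "code": "E11", "text": None,
         "date": "2019-01-01"},
        {"patient_id": "A", "coded": True, "code": "not-a-code", "text": None,
         "date": "2019-01-01"}])
    ledger = MappingLedger()
    ledger.add(MappingItem("medical_history", "E11", "e11", "ICD10", "ICD10", 1,
                           consensus=45100001, source_concept_id=45100001))
    rows, audit = build_observations(histories, ledger, {"A": 1}, make_sequences())
    assert len(rows) == 2
    assert rows["observation_concept_id"].tolist() == [45100001, 0]
    assert len(audit) == 1 and audit[0]["flag"] == "invalid_icd10"


# -- observation periods -----------------------------------------------------

def test_observation_period_extent_and_absence():
    visits = pd.DataFrame([{"person_id": 1, "visit_start_date": "2015-03-01"},
                           {"person_id": 1, "visit_start_date": "2019-06-30"}])
    periods = derive_observation_periods([(visits, "visit_start_date")],
                                         make_sequences())
    assert len(periods) == 1
    row = periods.iloc[0]
    assert row["observation_period_start_date"] == "2015-03-01"
    assert row["observation_period_end_date"] == "2019-06-30"
    empty = derive_observation_periods(
        [(pd.DataFrame(columns=["person_id", "visit_start_date"]),
          "visit_start_date")], make_sequences())
    assert empty.empty  # persons with zero events get no period


def test_observation_period_matches_manifest_extents(clean_pipeline):
    res = clean_pipeline
    by_person = {r.person_id: (r.observation_period_start_date,
                               r.observation_period_end_date)
                 for r in res.cdm["observation_period"].itertuples(index=False)}
    person_ids = {r.person_source_value: r.person_id
                  for r in res.cdm["person"].itertuples(index=False)}
    expected = res.manifest.per_patient_event_date_extents
    assert len(by_person) == len(expected)
    for source_pid, extent in expected.items():
        assert by_person[person_ids[source_pid]] == tuple(extent)


# -- drug eras ---------------------------------------------------------------

def _exposures(rows):
    return pd.DataFrame([{
        "drug_exposure_id": i + 1, "person_id": p, "drug_concept_id": c,
        "drug_exposure_start_date": s, "drug_exposure_end_date": e}
        for i, (p, c, s, e) in enumerate(rows)])


def _ingredient_store():
    store = ConceptStore()
    store.add_concept(Concept(100, "ing-a", "RxNorm", "a", True, "Drug"))
    store.add_concept(Concept(101, "ing-b", "RxNorm", "b", True, "Drug"))
    store.add_concept(Concept(200, "combo", "RxNorm", "ab", True, "Drug"))
    store.add_relationship(200, 100, "RxNorm has ingredient")
    store.add_relationship(200, 101, "RxNorm has ingredient")
    return store


def test_era_merge_within_window():
    store = _ingredient_store()
    exp = _exposures([(1, 100, "2020-01-01", "2020-01-10"),
                      (1, 100, "2020-01-25", "2020-02-05")])
    eras, _ = derive_drug_eras(exp, store, EraConfig(persistence_window=30),
                               make_sequences())
    assert len(eras) == 1                      # gap of 15 days ≤ 30
    row = eras.iloc[0]
    assert row["drug_era_start_date"] == "2020-01-01"
    assert row["drug_era_end_date"] == "2020-02-05"
    assert row["drug_exposure_count"] == 2
    assert row["gap_days"] == 14               # Jan 11 .. Jan 24 uncovered


def test_era_split_beyond_window():
    store = _ingredient_store()
    exp = _exposures([(1, 100, "2020-01-01", "2020-01-10"),
                      (1, 100, "2020-01-25", "2020-02-05")])
    eras, _ = derive_drug_eras(exp, store, EraConfig(persistence_window=10),
                               make_sequences())
    assert len(eras) == 2                      # gap of 15 days > 10


def test_combination_product_yields_two_eras():
    store = _ingredient_store()
    exp = _exposures([(1, 200, "2020-01-01", "2020-01-10")])
    eras, _ = derive_drug_eras(exp, store, EraConfig(), make_sequences())
    assert len(eras) == 2
    assert set(eras["drug_concept_id"]) == {100, 101}


def test_era_end_before_start_excluded_and_flagged():
    store = _ingredient_store()
    exp = _exposures([(1, 100, "2020-02-01", "2020-01-01")])
    eras, audit = derive_drug_eras(exp, store, EraConfig(), make_sequences())
    assert eras.empty
    assert audit and audit[0]["flag"] == "exposure_end_before_start"


# -- whole-build properties --------------------------------------------------

def test_pseudonymization(clean_pipeline):
    cdm = clean_pipeline.cdm
    persons = cdm["person"]
    assert list(persons["person_id"]) == list(range(1, len(persons) + 1))
    source_ids = set(persons["person_source_value"])
    for name, frame in cdm.tables.items():
        for col in frame.columns:
            if col.endswith("_source_value") or col == "note_text":
                continue
            values = set(frame[col].dropna().astype(str))
            assert not (values & source_ids), f"source id leaked into {name}.{col}"


def test_conservation_rows_in_equals_out_plus_rejections(clean_pipeline):
    res = clean_pipeline
    n_in = len(res.staging.biometrics) + len(res.staging.lab_results)
    assert n_in == len(res.cdm["measurement"]) + len(res.cdm.measurement_rejects)
    assert len(res.staging.prescriptions) == (len(res.cdm["drug_exposure"])
                                              + len(res.cdm.drug_rejects))


def test_build_deterministic(small_export):
    export, _ = small_export
    staging = extract_all(export)

    def build():
        store = bundled_store()
        ledger, _ = build_ledger(staging, store)
        return build_cdm(staging, ledger, store)

    a, b = build(), build()
    for name in a.tables:
        pd.testing.assert_frame_equal(a[name], b[name])
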