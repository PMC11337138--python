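"""Extraction: lossless parsing, raw fidelity, atomicity, profiling."""

import pandas as pd
import pytest

from caretl import extract_all, parse_patient_document, profile_staging
from caretl.errors import IntegrityError, InputError, ParseError, SchemaError
from caretl.extract import StagingStore, STAGING_TABLES, _COLUMNS

DOC = b"""<?xml version='1.0' encoding='UTF-8'?>
<patient id="P1" schema-version="1.0">
  <demographics><sex>F</sex><year-of-birth>1970</year-of-birth>
    <town>Lille</town><country>FR</country></demographics>
  <registration physician="dr-01" date="2015-01-01"/>
  <addresses><address line="1 rue A" town="Lille" zip="59000"/></addresses>
  <consultations>
    <consultation id="P1-c0" date="2015-03-01">
      <reason>Fievre</reason>
      <interview>Pas de signe de gravite</interview>
      <examination>
        <biometric variable="Poids" value="71.5" unit="kg"/>
        <biometric variable="Taille" value="172" unit="cm"/>
      </examination>
      <outcome>
        <diagnosis>Syndrome grippal</diagnosis>
        <prescription cip="3400930000000" days-supply="7" quantity="1" refills="0"/>
      </outcome>
    </consultation>
  </consultations>
  <lab-results/>
  <medical-history>
    <history coded="true" code="E11" date="2014-01-01"/>
    <history coded="false" date="2014-02-01">tabagisme sevre</history>
  </medical-history>
  <clinical-reports/>
</patient>
"""


def test_parse_count_conservation():
    records = parse_patient_document(DOC)
    assert len(records["patients"]) == 1
    assert len(records["consultations"]) == 1
    assert len(records["biometrics"]) == 2
    assert len(records["prescriptions"]) == 1
    # reason + interview + diagnosis
    assert [n["provenance"] for n in records["notes"]] == [
        "reason", "interview", "diagnosis"]
    assert len(records["histories"]) == 2


def test_parse_empty_patient():
    doc = (b"<?xml version='1.0'?><patient id='P9' schema-version='1.0'>"
           b"<demographics><sex>M</sex></demographics></patient>")
    records = parse_patient_document(doc)
    assert len(records["patients"]) == 1
    assert all(not records[t] for t in STAGING_TABLES if t != "patients")


def test_parse_rejects_malformed_xml(tmp_path):
    bad = tmp_path / "bad.xml"
    bad.write_text("<patient id='x'")
    with pytest.raises(ParseError, match="bad.xml"):
        parse_patient_document(bad)


def test_parse_rejects_unknown_schema_version():
    doc = b"<patient id='P1' schema-version='9.9'/>"
    with pytest.raises(SchemaError, match="9.9"):
        parse_patient_document(doc)


def test_unparseable_date_kept_and_flagged():
    doc = (b"<patient id='P1' schema-version='1.0'>"
           b"<demographics><sex>M</sex></demographics>"
           b"<consultations><consultation id='c1' date='sometime'>"
           b"<reason>x</reason></consultation></consultations></patient>")
    records = parse_patient_document(doc)
    row = records["consultations"][0]
    assert row["date_raw"] == "sometime" and row["date"] is None and not row["date_ok"]
    assert any("unparseable date" in w for w in records["_warnings"])


def test_extract_all_counts_match_manifest(small_export, tmp_path):
    export, manifest = small_export
    out = export.write(tmp_path / "exp")
    staging = extract_all(out)
    counts = staging.counts()
    assert counts["patients"] == manifest.true_n_patients
    assert counts["consultations"] == manifest.true_n_consultations
    assert counts["biometrics"] == manifest.true_n_biometrics
    assert counts["lab_results"] == manifest.true_n_lab_results
    assert counts["prescriptions"] == manifest.true_n_prescriptions
    assert counts["deaths"] == manifest.true_n_deaths
    coded = int(staging.histories["coded"].sum())
    assert coded == manifest.true_n_coded_histories
    free_items = len(staging.notes) + (len(staging.histories) - coded)
    assert free_items == manifest.true_n_free_text_items


def test_extract_raw_fidelity(small_export):
    export, _ = small_export
    staging = extract_all(export)
    raw_xml = b"".join(export.to_bytes(pid) for pid in export.patient_ids)
    for label in staging.lab_results["variable"].dropna().unique():
        assert label.encode("utf-8") in raw_xml


def test_extract_duplicate_patient_rejected(tmp_path):
    (tmp_path / "a.xml").write_bytes(DOC)
    (tmp_path / "b.xml").write_bytes(DOC)
    with pytest.raises(IntegrityError, match="P1"):
        extract_all(tmp_path)


def test_extract_duplicate_consultation_rejected():
    doc = (b"<patient id='P1' schema-version='1.0'>"
           b"<demographics><sex>M</sex></demographics>"
           b"<consultations>"
           b"<consultation id='c1' date='2015-01-01'/>"
           b"<consultation id='c1' date='2015-01-02'/>"
           b"</consultations></patient>")
    with pytest.raises(IntegrityError, match="duplicate consultation"):
        parse_patient_document(doc)


def test_extract_corrupt_file_is_atomic(tmp_path):
    (tmp_path / "a.xml").write_bytes(DOC)
    (tmp_path / "z.xml").write_text("<broken")
    with pytest.raises(ParseError, match="z.xml"):
        extract_all(tmp_path)


def test_extract_empty_directory(tmp_path):
    with pytest.raises(InputError):
        extract_all(tmp_path)


def test_extract_deterministic(small_export, tmp_path):
    export, _ = small_export
    out = export.write(tmp_path / "exp")
    a, b = extract_all(out), extract_all(out)
    for name in STAGING_TABLES:
        pd.testing.assert_frame_equal(a.table(name), b.table(name))


# -- profiling ---------------------------------------------------------------

def _store_with(patients_rows):
    frames = {t: pd.DataFrame(columns=_COLUMNS[t]) for t in STAGING_TABLES}
    frames["patients"] = pd.DataFrame(patients_rows, columns=_COLUMNS["patients"])
    return StagingStore(**frames)


def test_profile_distinct_and_top():
    store = _store_with([
        {"patient_id": "a", "sex": "M"}, {"patient_id": "a2", "sex": "M"},
        {"patient_id": "b", "sex": "F"}])
    report = profile_staging(store)
    profile = report["patients"]["sex"]
    assert profile.n_distinct == 2
    assert profile.top_values[0] == ("M", 2)
    assert sum(c for _v, c in profile.top_values) == 3


def test_profile_all_null_field():
    store = _store_with([{"patient_id": "a"}, {"patient_id": "b"}])
    report = profile_staging(store)
    assert report["patients"]["town"].null_fraction == 1.0
    assert report["patients"]["patient_id"].null_fraction == 0.0


def test_profile_covers_every_table_and_field(small_export):
    export, _ = small_export
    staging = extract_all(export)
    report = profile_staging(staging)
    for table in STAGING_TABLES:
        assert set(report[table]) == set(staging.table(table).columns)


def test_profile_type_inference(small_export):
    export, _ = small_export
    staging = extract_all(export)
    report = profile_staging(staging)
    assert report["consultations"]["date"].inferred_type == "date"
    assert report["biometrics"]["value"].inferred_type in ("real", "integer")
    assert report["notes"]["text"].inferred_type == "text"
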