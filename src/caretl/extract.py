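"""Parse the per-patient XML export into normalized staging tables.

The extractor is deliberately dumb: raw labels, codes and values are staged
byte-for-byte as they appear in the source documents (semantic judgement
belongs to the mapping and quality layers), and unparseable dates are kept
raw and flagged rather than rejected, so the completeness checks can see
them. It also profiles the staging tables — per-field type, null fraction,
distinct count and top value frequencies — as a minimal stand-in for a
White-Rabbit-style scan report.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from lxml import etree

from .errors import IntegrityError, InputError, ParseError, SchemaError
from .synthetic_source import SCHEMA_VERSION, SourceExport

STAGING_TABLES = ("patients", "consultations", "biometrics", "lab_results",
                  "prescriptions", "histories", "notes", "addresses", "deaths",
                  "providers")

#: provenance classes of free-text items (consultation steps and beyond)
NOTE_PROVENANCES = ("reason", "interview", "diagnosis", "referral", "vaccination",
                    "supplementary", "clinical_report", "history")

_COLUMNS = {
    "patients": ["patient_id", "sex", "year_of_birth", "town", "country",
                 "physician", "registration_date"],
    "consultations": ["patient_id", "consultation_id", "date_raw", "date", "date_ok"],
    "biometrics": ["patient_id", "consultation_id", "date", "variable", "value", "unit"],
    "lab_results": ["patient_id", "result_set_id", "laboratory", "date",
                    "consultation_ref", "variable", "value", "unit"],
    "prescriptions": ["patient_id", "consultation_id", "date", "cip_code",
                      "days_supply", "quantity", "refills"],
    "histories": ["patient_id", "coded", "code", "text", "date"],
    "notes": ["patient_id", "consultation_id", "date", "provenance", "text"],
    "addresses": ["patient_id", "line", "town", "zip"],
    "deaths": ["patient_id", "death_date"],
    "providers": ["physician"],
}


@dataclass
class StagingStore:
    """Normalized staging tables plus the parse warnings collected on the way."""

    patients: pd.DataFrame
    consultations: pd.DataFrame
    biometrics: pd.DataFrame
    lab_results: pd.DataFrame
    prescriptions: pd.DataFrame
    histories: pd.DataFrame
    notes: pd.DataFrame
    addresses: pd.DataFrame
    deaths: pd.DataFrame
    providers: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def counts(self) -> dict[str, int]:
        return {name: len(self.table(name)) for name in STAGING_TABLES}


def _parse_date(raw: str | None, warnings: list[str], context: str):
    if raw is None:
        warnings.append(f"{context}: missing date")
        return None
    try:
        return dt.date.fromisoformat(raw).isoformat()
    except ValueError:
        warnings.append(f"{context}: unparseable date {raw!r}")
        return None


def parse_patient_document(source: str | Path | bytes) -> dict[str, list[dict]]:
    """Parse one patient XML document into per-entity staging records.

    ``source`` is a file path or raw bytes. Raises :class:`ParseError` for
    non-well-formed XML and :class:`SchemaError` for an unknown schema
    version or root element.
    """
    name = str(source) if not isinstance(source, bytes) else "<bytes>"
    try:
        if isinstance(source, bytes):
            root = etree.fromstring(source)
        else:
            root = etree.parse(str(source)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"not well-formed XML: {name}: {exc}") from exc

    if root.tag != "patient":
        raise SchemaError(f"{name}: unexpected root element <{root.tag}>")
    version = root.get("schema-version")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"{name}: unknown schema version {version!r} "
                          f"(expected {SCHEMA_VERSION})")

    warnings: list[str] = []
    pid = root.get("id")
    if not pid:
        raise SchemaError(f"{name}: patient element lacks an id")

    records: dict[str, list[dict]] = {t: [] for t in STAGING_TABLES}

    def text_of(path):
        el = root.find(path)
        return el.text if el is not None else None

    reg = root.find("registration")
    records["patients"].append({
        "patient_id": pid,
        "sex": text_of("demographics/sex"),
        "year_of_birth": text_of("demographics/year-of-birth"),
        "town": text_of("demographics/town"),
        "country": text_of("demographics/country"),
        "physician": reg.get("physician") if reg is not None else None,
        "registration_date": _parse_date(reg.get("date"), warnings, f"{pid}/registration")
        if reg is not None else None,
    })

    for addr in root.iterfind("addresses/address"):
        records["addresses"].append({"patient_id": pid, "line": addr.get("line"),
                                     "town": addr.get("town"), "zip": addr.get("zip")})

    seen_cids: set[str] = set()
    for c in root.iterfind("consultations/consultation"):
        cid = c.get("id")
        if cid in seen_cids:
            raise IntegrityError(f"{pid}: duplicate consultation id {cid!r}")
        seen_cids.add(cid)
        raw_date = c.get("date")
        date = _parse_date(raw_date, warnings, f"{pid}/{cid}")
        records["consultations"].append({
            "patient_id": pid, "consultation_id": cid,
            "date_raw": raw_date, "date": date, "date_ok": date is not None})
        for tag in ("reason", "interview"):
            el = c.find(tag)
            if el is not None and el.text:
                records["notes"].append({"patient_id": pid, "consultation_id": cid,
                                         "date": date, "provenance": tag, "text": el.text})
        for b in c.iterfind("examination/biometric"):
            records["biometrics"].append({
                "patient_id": pid, "consultation_id": cid, "date": date,
                "variable": b.get("variable"), "value": b.get("value"),
                "unit": b.get("unit")})
        for tag, provenance in (("diagnosis", "diagnosis"), ("referral", "referral"),
                                ("vaccination", "vaccination"),
                                ("supplementary", "supplementary")):
            for el in c.iterfind(f"outcome/{tag}"):
                records["notes"].append({"patient_id": pid, "consultation_id": cid,
                                         "date": date, "provenance": provenance,
                                         "text": el.text})
        for p in c.iterfind("outcome/prescription"):
            records["prescriptions"].append({
                "patient_id": pid, "consultation_id": cid, "date": date,
                "cip_code": p.get("cip"), "days_supply": p.get("days-supply"),
                "quantity": p.get("quantity"), "refills": p.get("refills")})

    for rs in root.iterfind("lab-results/result-set"):
        date = _parse_date(rs.get("date"), warnings, f"{pid}/{rs.get('id')}")
        for r in rs.iterfind("result"):
            records["lab_results"].append({
                "patient_id": pid, "result_set_id": rs.get("id"),
                "laboratory": rs.get("laboratory"), "date": date,
                "consultation_ref": rs.get("consultation-ref"),
                "variable": r.get("variable"), "value": r.get("value"),
                "unit": r.get("unit")})

    for h in root.iterfind("medical-history/history"):
        date = _parse_date(h.get("date"), warnings, f"{pid}/history")
        records["histories"].append({
            "patient_id": pid, "coded": h.get("coded") == "true",
            "code": h.get("code"), "text": h.text, "date": date})

    for r in root.iterfind("clinical-reports/report"):
        date = _parse_date(r.get("date"), warnings, f"{pid}/report")
        records["notes"].append({"patient_id": pid, "consultation_id": None,
                                 "date": date, "provenance": "clinical_report",
                                 "text": r.text})

    death = root.find("death")
    if death is not None:
        records["deaths"].append({
            "patient_id": pid,
            "death_date": _parse_date(death.get("date"), warnings, f"{pid}/death")})

    records["_warnings"] = warnings  # type: ignore[assignment]
    return records


def extract_all(source: str | Path | SourceExport) -> StagingStore:
    """Extract every patient document of an export directory (or in-memory
    export) into one :class:`StagingStore`.

    Atomic: a corrupt document aborts the whole extraction with an error
    naming the file; duplicate patient identifiers are rejected.
    """
    if isinstance(source, SourceExport):
        docs: list[tuple[str, bytes]] = [(f"<memory:{pid}>", source.to_bytes(pid))
                                         for pid in source.patient_ids]
    else:
        directory = Path(source)
        files = sorted(directory.glob("*.xml"))
        if not files:
            raise InputError(f"no patient documents (*.xml) found in {directory}")
        docs = [(str(f), f.read_bytes()) for f in files]

    tables: dict[str, list[dict]] = {t: [] for t in STAGING_TABLES}
    warnings: list[str] = []
    seen_pids: set[str] = set()
    for name, payload in docs:
        try:
            records = parse_patient_document(payload)
        except (ParseError, SchemaError) as exc:
            raise type(exc)(f"{name}: {exc}") from exc
        pid = records["patients"][0]["patient_id"]
        if pid in seen_pids:
            raise IntegrityError(f"duplicate patient identifier {pid!r} in {name}")
        seen_pids.add(pid)
        warnings.extend(records.pop("_warnings"))  # type: ignore[arg-type]
        for t in STAGING_TABLES:
            tables[t].extend(records[t])

    physicians = sorted({p["physician"] for p in tables["patients"] if p["physician"]})
    tables["providers"] = [{"physician": ph} for ph in physicians]

    frames = {t: pd.DataFrame(tables[t], columns=_COLUMNS[t]) for t in STAGING_TABLES}
    return StagingStore(**frames, warnings=warnings)


def save_staging(store: StagingStore, directory: str | Path) -> Path:
    """Materialize the staging tables as one CSV per entity."""
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    for name in STAGING_TABLES:
        store.table(name).to_csv(out / f"{name}.csv", index=False)
    (out / "warnings.txt").write_text("\n".join(store.warnings), encoding="utf-8")
    return out


def load_staging(directory: str | Path) -> StagingStore:
    directory = Path(directory)
    frames = {}
    for name in STAGING_TABLES:
        df = pd.read_csv(directory / f"{name}.csv", dtype=str,
                         keep_default_na=False).replace({"": None})
        df = df.reindex(columns=_COLUMNS[name])
        if name == "histories":
            df["coded"] = df["coded"] == "True"
        if name == "consultations":
            df["date_ok"] = df["date_ok"] == "True"
        frames[name] = df
    warnings_file = directory / "warnings.txt"
    warnings = (warnings_file.read_text(encoding="utf-8").splitlines()
                if warnings_file.exists() else [])
    return StagingStore(**frames, warnings=[w for w in warnings if w])


# ---------------------------------------------------------------------------
# profiling (scan report)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldProfile:
    inferred_type: str
    null_fraction: float
    n_distinct: int
    top_values: tuple[tuple[str, int], ...]


ScanReport = dict[str, dict[str, FieldProfile]]


def _infer_type(series: pd.Series) -> str:
    values = series.dropna()
    if values.empty:
        return "empty"
    as_num = pd.to_numeric(values, errors="coerce")
    if as_num.notna().all():
        return "integer" if (as_num == as_num.round()).all() else "real"
    try:
        values.map(dt.date.fromisoformat)
        return "date"
    except (ValueError, TypeError):
        return "text"


def profile_staging(store: StagingStore, top_k: int = 10) -> ScanReport:
    """Profile every staging table and field.

    Null fractions are exact; value frequencies sum to the non-null row
    count; an all-null field reports a null fraction of 1.0.
    """
    report: ScanReport = {}
    for table in STAGING_TABLES:
        df = store.table(table)
        fields = {}
        for col in df.columns:
            series = df[col]
            n = len(series)
            nulls = int(series.isna().sum())
            counts = series.dropna().astype(str).value_counts()
            fields[col] = FieldProfile(
                inferred_type=_infer_type(series),
                null_fraction=(nulls / n) if n else 1.0,
                n_distinct=int(counts.size),
                top_values=tuple((v, int(c)) for v, c in counts.head(top_k).items()),
            )
        report[table] = fields
    return report
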