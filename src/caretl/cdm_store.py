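"""Materialize the OMOP CDM v5.4 subset in an embedded relational database.

The subset covers the 12 clinical/administrative tables plus the three
vocabulary tables (CONCEPT, CONCEPT_RELATIONSHIP, VOCABULARY), and one
toolkit-specific ``etl_audit`` side table for structural anomalies the CDM
cannot express. SQLite (stdlib ``sqlite3``) is the embedded backend; the DDL
is portable SQL, also shipped as a versioned file under ``sql/``.

Loading is constraint-enforced twice: a pre-load validator itemizes primary
key, foreign key and required-column violations before insertion, and the
database runs with ``PRAGMA foreign_keys = ON`` so anything the validator
lets through is still caught. Load order is fixed — vocabulary first, then
persons/locations/providers/care site, then visits, event tables and the
derived tables.
"""

from __future__ import annotations

import sqlite3
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import OrderingError, SchemaExistsError
from .vocabulary import ConceptStore

SCHEMA_VERSION = "5.4-subset-1"

_SQL_DIR = Path(__file__).parent / "sql"


@dataclass(frozen=True)
class Column:
    name: str
    type: str          # INTEGER | REAL | TEXT | DATE (DATE stored as ISO TEXT)
    required: bool = False


@dataclass(frozen=True)
class Table:
    name: str
    columns: tuple[Column, ...]
    primary_key: str | None
    foreign_keys: tuple[tuple[str, str, str], ...] = ()  # (column, ref table, ref column)


def _t(name, pk, cols, fks=()):
    return Table(name, tuple(Column(*c) for c in cols), pk, tuple(fks))


#: the OMOP CDM v5.4 subset plus the toolkit's audit side table
SCHEMA: tuple[Table, ...] = (
    _t("vocabulary", "vocabulary_id",
       [("vocabulary_id", "TEXT", True), ("vocabulary_name", "TEXT", True)]),
    _t("concept", "concept_id",
       [("concept_id", "INTEGER", True), ("concept_name", "TEXT", True),
        ("domain_id", "TEXT", True), ("vocabulary_id", "TEXT", True),
        ("concept_code", "TEXT", True), ("standard_concept", "TEXT", False)],
       [("vocabulary_id", "vocabulary", "vocabulary_id")]),
    _t("concept_relationship", None,
       [("concept_id_1", "INTEGER", True), ("concept_id_2", "INTEGER", True),
        ("relationship_id", "TEXT", True)],
       [("concept_id_1", "concept", "concept_id"),
        ("concept_id_2", "concept", "concept_id")]),
    _t("location", "location_id",
       [("location_id", "INTEGER", True), ("city", "TEXT", False),
        ("zip", "TEXT", False), ("location_source_value", "TEXT", False)]),
    _t("care_site", "care_site_id",
       [("care_site_id", "INTEGER", True), ("care_site_name", "TEXT", False),
        ("place_of_service_concept_id", "INTEGER", False),
        ("care_site_source_value", "TEXT", False)]),
    _t("provider", "provider_id",
       [("provider_id", "INTEGER", True), ("provider_name", "TEXT", False),
        ("care_site_id", "INTEGER", False), ("provider_source_value", "TEXT", False)],
       [("care_site_id", "care_site", "care_site_id")]),
    _t("person", "person_id",
       [("person_id", "INTEGER", True), ("gender_concept_id", "INTEGER", True),
        ("year_of_birth", "INTEGER", False), ("race_concept_id", "INTEGER", True),
        ("ethnicity_concept_id", "INTEGER", True), ("location_id", "INTEGER", False),
        ("provider_id", "INTEGER", False), ("care_site_id", "INTEGER", False),
        ("person_source_value", "TEXT", False), ("gender_source_value", "TEXT", False)],
       [("gender_concept_id", "concept", "concept_id"),
        ("location_id", "location", "location_id"),
        ("provider_id", "provider", "provider_id"),
        ("care_site_id", "care_site", "care_site_id")]),
    _t("observation_period", "observation_period_id",
       [("observation_period_id", "INTEGER", True), ("person_id", "INTEGER", True),
        ("observation_period_start_date", "DATE", True),
        ("observation_period_end_date", "DATE", True),
        ("period_type_concept_id", "INTEGER", True)],
       [("person_id", "person", "person_id"),
        ("period_type_concept_id", "concept", "concept_id")]),
    _t("visit_occurrence", "visit_occurrence_id",
       [("visit_occurrence_id", "INTEGER", True), ("person_id", "INTEGER", True),
        ("visit_concept_id", "INTEGER", True), ("visit_start_date", "DATE", True),
        ("visit_end_date", "DATE", True), ("visit_type_concept_id", "INTEGER", True),
        ("provider_id", "INTEGER", False), ("care_site_id", "INTEGER", False),
        ("visit_source_value", "TEXT", False)],
       [("person_id", "person", "person_id"),
        ("visit_concept_id", "concept", "concept_id"),
        ("provider_id", "provider", "provider_id"),
        ("care_site_id", "care_site", "care_site_id")]),
    _t("measurement", "measurement_id",
       [("measurement_id", "INTEGER", True), ("person_id", "INTEGER", True),
        ("measurement_concept_id", "INTEGER", True), ("measurement_date", "DATE", True),
        ("measurement_type_concept_id", "INTEGER", True),
        ("value_as_number", "REAL", False), ("unit_concept_id", "INTEGER", False),
        ("visit_occurrence_id", "INTEGER", False),
        ("measurement_source_value", "TEXT", False),
        ("measurement_source_concept_id", "INTEGER", False),
        ("unit_source_value", "TEXT", False)],
       [("person_id", "person", "person_id"),
        ("measurement_concept_id", "concept", "concept_id"),
        ("visit_occurrence_id", "visit_occurrence", "visit_occurrence_id")]),
    _t("drug_exposure", "drug_exposure_id",
       [("drug_exposure_id", "INTEGER", True), ("person_id", "INTEGER", True),
        ("drug_concept_id", "INTEGER", True),
        ("drug_exposure_start_date", "DATE", True),
        ("drug_exposure_end_date", "DATE", True),
        ("drug_type_concept_id", "INTEGER", True), ("quantity", "REAL", False),
        ("days_supply", "INTEGER", False), ("refills", "INTEGER", False),
        ("visit_occurrence_id", "INTEGER", False), ("drug_source_value", "TEXT", False),
        ("drug_source_concept_id", "INTEGER", False)],
       [("person_id", "person", "person_id"),
        ("drug_concept_id", "concept", "concept_id"),
        ("visit_occurrence_id", "visit_occurrence", "visit_occurrence_id")]),
    _t("drug_era", "drug_era_id",
       [("drug_era_id", "INTEGER", True), ("person_id", "INTEGER", True),
        ("drug_concept_id", "INTEGER", True), ("drug_era_start_date", "DATE", True),
        ("drug_era_end_date", "DATE", True), ("drug_exposure_count", "INTEGER", False),
        ("gap_days", "INTEGER", False)],
       [("person_id", "person", "person_id"),
        ("drug_concept_id", "concept", "concept_id")]),
    _t("note", "note_id",
       [("note_id", "INTEGER", True), ("person_id", "INTEGER", True),
        ("note_date", "DATE", False), ("note_type_concept_id", "INTEGER", True),
        ("note_class_concept_id", "INTEGER", True), ("note_title", "TEXT", False),
        ("note_text", "TEXT", True), ("encoding_concept_id", "INTEGER", True),
        ("language_concept_id", "INTEGER", True),
        ("visit_occurrence_id", "INTEGER", False), ("note_source_value", "TEXT", False)],
       [("person_id", "person", "person_id"),
        ("visit_occurrence_id", "visit_occurrence", "visit_occurrence_id")]),
    _t("observation", "observation_id",
       [("observation_id", "INTEGER", True), ("person_id", "INTEGER", True),
        ("observation_concept_id", "INTEGER", True), ("observation_date", "DATE", True),
        ("observation_type_concept_id", "INTEGER", True),
        ("value_as_string", "TEXT", False), ("visit_occurrence_id", "INTEGER", False),
        ("observation_source_value", "TEXT", False),
        ("observation_source_concept_id", "INTEGER", False)],
       [("person_id", "person", "person_id"),
        ("observation_concept_id", "concept", "concept_id"),
        ("visit_occurrence_id", "visit_occurrence", "visit_occurrence_id")]),
    _t("death", "person_id",
       [("person_id", "INTEGER", True), ("death_date", "DATE", True),
        ("death_type_concept_id", "INTEGER", False)],
       [("person_id", "person", "person_id")]),
    _t("etl_audit", "audit_id",
       [("audit_id", "INTEGER", True), ("table_name", "TEXT", True),
        ("row_id", "INTEGER", False), ("flag", "TEXT", True),
        ("detail", "TEXT", False)]),
)

#: fixed load order: vocabulary → administrative → visits → events → derived
LOAD_ORDER = ("vocabulary", "concept", "concept_relationship", "location",
              "care_site", "provider", "person", "visit_occurrence", "measurement",
              "drug_exposure", "note", "observation", "death",
              "observation_period", "drug_era", "etl_audit")

VOCABULARY_TABLES = ("vocabulary", "concept", "concept_relationship")
OMOP_TABLE_COUNT = 15  # 12 clinical/administrative + 3 vocabulary tables


def schema_tables() -> dict[str, Table]:
    return {t.name: t for t in SCHEMA}


def ddl_script() -> str:
    """Portable CREATE TABLE statements for the whole subset."""
    lines = [f"-- OMOP CDM subset schema, version {SCHEMA_VERSION}"]
    for table in SCHEMA:
        cols = []
        for c in table.columns:
            sqltype = "TEXT" if c.type == "DATE" else c.type
            cols.append(f"  {c.name} {sqltype}{' NOT NULL' if c.required else ''}")
        if table.primary_key:
            cols.append(f"  PRIMARY KEY ({table.primary_key})")
        for col, ref_table, ref_col in table.foreign_keys:
            cols.append(f"  FOREIGN KEY ({col}) REFERENCES {ref_table} ({ref_col})")
        lines.append(f"CREATE TABLE {table.name} (\n" + ",\n".join(cols) + "\n);")
    return "\n\n".join(lines) + "\n"


def bundled_ddl() -> str:
    return (_SQL_DIR / "cdm_v54_subset.sql").read_text(encoding="utf-8")


def connect(path: str | Path | None = None) -> sqlite3.Connection:
    conn = sqlite3.connect(":memory:" if path is None else str(path))
    conn.execute("PRAGMA foreign_keys = ON")
    return conn


def create_schema(conn: sqlite3.Connection) -> dict[str, Table]:
    """Apply the schema; refuses to run against a non-empty target."""
    existing = {r[0] for r in conn.execute(
        "SELECT name FROM sqlite_master WHERE type='table'")}
    conflicts = existing & {t.name for t in SCHEMA}
    if conflicts:
        raise SchemaExistsError(f"tables already exist: {sorted(conflicts)}")
    conn.executescript(ddl_script())
    conn.commit()
    return schema_tables()


def introspect_schema(conn: sqlite3.Connection) -> dict[str, Table]:
    """Rebuild a :class:`Table` description from the live database."""
    out = {}
    names = [r[0] for r in conn.execute(
        "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name")]
    for name in names:
        cols, pk = [], None
        for _cid, cname, ctype, notnull, _dflt, ispk in conn.execute(
                f"PRAGMA table_info({name})"):
            cols.append(Column(cname, ctype, bool(notnull)))
            if ispk:
                pk = cname
        fks = tuple(sorted(
            (row[3], row[2], row[4]) for row in conn.execute(
                f"PRAGMA foreign_key_list({name})")))
        declared = schema_tables().get(name)
        if declared is not None:  # preserve declared column order & DATE typing
            cols = [Column(c.name, c.type, r.required)
                    for c, r in zip(declared.columns, cols)]
        out[name] = Table(name, tuple(cols), pk, fks)
    return out


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

@dataclass
class TableLoad:
    attempted: int
    loaded: int
    rejected: int
    seconds: float
    rejections: list[dict] = field(default_factory=list)


@dataclass
class LoadReport:
    tables: dict[str, TableLoad] = field(default_factory=dict)

    @property
    def total_loaded(self) -> int:
        return sum(t.loaded for t in self.tables.values())

    @property
    def total_rejected(self) -> int:
        return sum(t.rejected for t in self.tables.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"table": name, "attempted": t.attempted, "loaded": t.loaded,
             "rejected": t.rejected, "seconds": round(t.seconds, 4)}
            for name, t in self.tables.items()])


def validate_rows(table: Table, rows: list[dict],
                  existing_keys: dict[str, set]) -> tuple[list[dict], list[dict]]:
    """Pre-load validator mirroring the database constraints exactly.

    Checks required columns, primary-key uniqueness (against the batch and
    the already-loaded content) and foreign-key resolution. Returns
    (valid rows, itemized rejections).
    """
    valid, rejected = [], []
    seen_pk: set = set()
    fk_targets = {col: existing_keys.get(ref_table, set())
                  for col, ref_table, _ref_col in table.foreign_keys}
    required = [c.name for c in table.columns if c.required]
    for row in rows:
        reasons = []
        for col in required:
            if row.get(col) is None:
                reasons.append(f"required column {col} is null")
        if table.primary_key:
            pk = row.get(table.primary_key)
            if pk in seen_pk or pk in existing_keys.get(table.name, set()):
                reasons.append(f"duplicate primary key {table.primary_key}={pk}")
        for col, ref_table, _ref in table.foreign_keys:
            value = row.get(col)
            if value is not None and value not in fk_targets[col]:
                reasons.append(f"foreign key {ref_table.upper()}: "
                               f"{col}={value} not found")
        if reasons:
            rejected.append({"row": row, "reasons": reasons})
        else:
            if table.primary_key:
                seen_pk.add(row.get(table.primary_key))
            valid.append(row)
    return valid, rejected


def _rows_of(frame: pd.DataFrame, table: Table) -> list[dict]:
    cols = [c.name for c in table.columns]
    sub = frame.reindex(columns=cols)
    sub = sub.astype(object).where(pd.notna(sub), None)
    return sub.to_dict("records")


def load_cdm(tables: dict[str, pd.DataFrame], conn: sqlite3.Connection) -> LoadReport:
    """Load DataFrames into the schema under constraint enforcement.

    Vocabulary tables must be present (or already loaded) before any
    clinical table; violating rows are rejected and itemized, never
    partially inserted.
    """
    schema = schema_tables()
    unknown = set(tables) - set(schema)
    if unknown:
        raise OrderingError(f"unknown target tables: {sorted(unknown)}")

    n_concepts = conn.execute("SELECT COUNT(*) FROM concept").fetchone()[0]
    clinical = [t for t in tables if t not in VOCABULARY_TABLES and t != "etl_audit"]
    if clinical and n_concepts == 0 and "concept" not in tables:
        raise OrderingError("vocabulary tables must be loaded before clinical tables")

    existing_keys: dict[str, set] = {}

    def refresh_keys(name: str) -> None:
        table = schema[name]
        if table.primary_key:
            existing_keys[name] = {r[0] for r in conn.execute(
                f"SELECT {table.primary_key} FROM {name}")}

    for name in schema:
        refresh_keys(name)

    report = LoadReport()
    for name in LOAD_ORDER:
        if name not in tables:
            continue
        table = schema[name]
        rows = _rows_of(tables[name], table)
        t0 = time.perf_counter()
        valid, rejected = validate_rows(table, rows, existing_keys)
        if valid:
            cols = [c.name for c in table.columns]
            placeholders = ", ".join("?" for _ in cols)
            conn.executemany(
                f"INSERT INTO {name} ({', '.join(cols)}) VALUES ({placeholders})",
                [tuple(r[c] for c in cols) for r in valid])
        conn.commit()
        refresh_keys(name)
        report.tables[name] = TableLoad(
            attempted=len(rows), loaded=len(valid), rejected=len(rejected),
            seconds=time.perf_counter() - t0, rejections=rejected)
    return report


def load_concept_store(store: ConceptStore, conn: sqlite3.Connection) -> LoadReport:
    frames = store.to_frames()
    return load_cdm({"vocabulary": frames["VOCABULARY"],
                     "concept": frames["CONCEPT"],
                     "concept_relationship": frames["CONCEPT_RELATIONSHIP"]}, conn)
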