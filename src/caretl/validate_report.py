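"""Source-vs-warehouse validation queries and dashboard data export.

Five parameterized queries mirror how a clinician would check the warehouse
against the source software: two on general activity (patients per family
physician, consultations in a period), two on prescription data (patients
exposed to a given ATC drug class) and one on laboratory data (patients
with a value beyond a threshold). All counts are restricted to events on or
before the extraction cutoff date, the warehouse's content horizon. Results
are compared with the generator's ground-truth manifest; mismatches carry a
mandatory explanation slot, mirroring manual reconciliation.

The dashboard export produces the three datasets a practice-feedback
front-end needs — activity, prescriptions and laboratory distributions —
as plain CSV/JSON; the data contract, not any UI, is the deliverable.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import InputError
from .quality import DistributionSummary, value_distribution
from .cdm_transform import PlausibilityRanges, TYPE_LAB
from .synthetic_source import GroundTruthManifest


@dataclass(frozen=True)
class ValidationQuery:
    id: str
    category: str        # activity | prescription | laboratory
    description: str
    params: dict = field(default_factory=dict)


def default_queries() -> list[ValidationQuery]:
    """The five validation queries (2 activity, 2 prescription, 1 laboratory)."""
    return [
        ValidationQuery("q1", "activity",
                        "registered patients per family physician"),
        ValidationQuery("q2", "activity",
                        "consultations up to the cutoff date"),
        ValidationQuery("q3", "prescription",
                        "patients with >= 1 exposure to ATC A10BA02 (metformin)",
                        {"atc": "A10BA02"}),
        ValidationQuery("q4", "prescription",
                        "patients with >= 1 exposure to ATC C09AA05 (ramipril)",
                        {"atc": "C09AA05"}),
        ValidationQuery("q5", "laboratory",
                        "patients with a potassium value above threshold",
                        {"loinc": "2823-3", "threshold": 5.0}),
    ]


def _check_query_mix(queries: list[ValidationQuery]) -> None:
    mix = {"activity": 0, "prescription": 0, "laboratory": 0}
    for q in queries:
        if q.category not in mix:
            raise InputError(f"unknown query category {q.category!r}")
        mix[q.category] += 1
    if (mix["activity"], mix["prescription"], mix["laboratory"]) != (2, 2, 1):
        raise InputError("expected exactly 2 activity, 2 prescription and "
                         f"1 laboratory query, got {mix}")


def _concept_id(conn: sqlite3.Connection, vocabulary: str, code: str) -> int:
    row = conn.execute(
        "SELECT concept_id FROM concept WHERE vocabulary_id = ? AND concept_code = ?",
        (vocabulary, code)).fetchone()
    if row is None:
        raise LookupError(f"unknown {vocabulary} concept code {code!r}")
    return row[0]


def run_validation_queries(conn: sqlite3.Connection,
                           queries: list[ValidationQuery] | None = None,
                           cutoff_date: str = "2021-06-30") -> dict[str, object]:
    """Execute the validation queries against the warehouse.

    q1 excludes patients whose earliest observed event postdates the cutoff
    (the warehouse-side analogue of removing registrations after the
    extraction date); every other count is restricted to events on or
    before the cutoff.
    """
    if queries is None:
        queries = default_queries()
    _check_query_mix(queries)
    results: dict[str, object] = {}
    activity_seen = 0
    for q in queries:
        if q.category == "activity":
            activity_seen += 1
            if activity_seen == 1:
                rows = conn.execute(
                    "SELECT pr.provider_source_value, COUNT(*) FROM person p "
                    "JOIN provider pr ON pr.provider_id = p.provider_id "
                    "WHERE NOT EXISTS (SELECT 1 FROM observation_period op "
                    "  WHERE op.person_id = p.person_id "
                    "  AND op.observation_period_start_date > ?) "
                    "GROUP BY 1 ORDER BY 1", (cutoff_date,)).fetchall()
                results[q.id] = {phys: n for phys, n in rows}
            else:
                results[q.id] = conn.execute(
                    "SELECT COUNT(*) FROM visit_occurrence "
                    "WHERE visit_start_date <= ?", (cutoff_date,)).fetchone()[0]
        elif q.category == "prescription":
            atc_id = _concept_id(conn, "ATC", q.params["atc"])
            results[q.id] = conn.execute(
                "SELECT COUNT(DISTINCT d.person_id) FROM drug_exposure d "
                "WHERE d.drug_exposure_start_date <= ? AND d.drug_concept_id IN "
                "(SELECT concept_id_2 FROM concept_relationship "
                " WHERE concept_id_1 = ? AND relationship_id = 'ATC to RxNorm')",
                (cutoff_date, atc_id)).fetchone()[0]
        else:  # laboratory
            concept = _concept_id(conn, "LOINC", q.params["loinc"])
            results[q.id] = conn.execute(
                "SELECT COUNT(DISTINCT person_id) FROM measurement "
                "WHERE measurement_concept_id = ? AND value_as_number > ? "
                "AND measurement_date <= ?",
                (concept, q.params["threshold"], cutoff_date)).fetchone()[0]
    return results


# ---------------------------------------------------------------------------
# concordance with the source truth
# ---------------------------------------------------------------------------

@dataclass
class QueryConcordance:
    query_id: str
    warehouse_value: object
    source_value: object
    match: bool
    explanation: str | None = None


@dataclass
class ConcordanceReport:
    rows: list[QueryConcordance]

    @property
    def all_match(self) -> bool:
        return all(r.match for r in self.rows)

    @property
    def n_mismatches(self) -> int:
        return sum(not r.match for r in self.rows)

    def explain(self, query_id: str, explanation: str) -> None:
        for r in self.rows:
            if r.query_id == query_id:
                r.explanation = explanation
                return
        raise InputError(f"no concordance row for query {query_id!r}")

    def unexplained_mismatches(self) -> list[str]:
        return [r.query_id for r in self.rows if not r.match and not r.explanation]


def source_truth_values(manifest: GroundTruthManifest,
                        queries: list[ValidationQuery] | None = None) -> dict[str, object]:
    """Read the source-side answers off the ground-truth manifest."""
    if queries is None:
        queries = default_queries()
    truth = manifest.source_truth
    out: dict[str, object] = {}
    activity_seen = 0
    for q in queries:
        if q.category == "activity":
            activity_seen += 1
            out[q.id] = (dict(truth["patients_per_physician"]) if activity_seen == 1
                         else truth["n_consultations"])
        elif q.category == "prescription":
            out[q.id] = truth["patients_on_atc"].get(q.params["atc"], 0)
        else:
            if q.params["threshold"] != truth["high_potassium"]["threshold"]:
                raise InputError("laboratory query threshold differs from the "
                                 "threshold recorded in the manifest")
            out[q.id] = truth["high_potassium"]["n_patients"]
    return out


def compare_to_source(results: dict[str, object],
                      manifest: GroundTruthManifest,
                      queries: list[ValidationQuery] | None = None) -> ConcordanceReport:
    """Per-query concordance between warehouse results and source truth."""
    truth = source_truth_values(manifest, queries)
    rows = [QueryConcordance(qid, results.get(qid), truth[qid],
                             results.get(qid) == truth[qid])
            for qid in truth]
    return ConcordanceReport(rows)


# ---------------------------------------------------------------------------
# dashboard data export
# ---------------------------------------------------------------------------

def export_dashboard_data(conn: sqlite3.Connection,
                          out_dir: str | Path | None = None,
                          ranges: PlausibilityRanges | None = None) -> dict[str, pd.DataFrame]:
    """The three dashboard datasets: activity, prescriptions, laboratory.

    * activity — patients and consultations per physician per year;
    * prescriptions — exposure counts per ATC class per year;
    * laboratory — the value distribution per laboratory analyte.
    """
    activity = pd.read_sql_query(
        "SELECT COALESCE(pr.provider_source_value, '(none)') AS physician, "
        "substr(v.visit_start_date, 1, 4) AS year, "
        "COUNT(DISTINCT v.person_id) AS n_patients, COUNT(*) AS n_consultations "
        "FROM visit_occurrence v LEFT JOIN provider pr "
        "ON pr.provider_id = v.provider_id GROUP BY 1, 2 ORDER BY 1, 2", conn)

    prescriptions = pd.read_sql_query(
        "SELECT a.concept_code AS atc_code, a.concept_name AS atc_name, "
        "substr(d.drug_exposure_start_date, 1, 4) AS year, "
        "COUNT(*) AS n_exposures FROM drug_exposure d "
        "JOIN concept_relationship cr ON cr.concept_id_2 = d.drug_concept_id "
        " AND cr.relationship_id = 'ATC to RxNorm' "
        "JOIN concept a ON a.concept_id = cr.concept_id_1 "
        "GROUP BY 1, 2, 3 ORDER BY 1, 3", conn)

    lab_concepts = [r[0] for r in conn.execute(
        "SELECT DISTINCT measurement_concept_id FROM measurement "
        "WHERE measurement_type_concept_id = ? AND measurement_concept_id != 0 "
        "ORDER BY 1", (TYPE_LAB,))]
    lab_rows = []
    for concept_id in lab_concepts:
        name = conn.execute("SELECT concept_name FROM concept WHERE concept_id = ?",
                            (concept_id,)).fetchone()
        d: DistributionSummary = value_distribution(conn, concept_id, ranges)
        lab_rows.append({"concept_id": concept_id,
                         "concept_name": name[0] if name else "",
                         "n": d.n, "min": d.minimum, "p25": d.p25,
                         "median": d.median, "p75": d.p75, "max": d.maximum,
                         "out_of_range": d.out_of_range})
    laboratory = pd.DataFrame(lab_rows, columns=["concept_id", "concept_name", "n",
                                                 "min", "p25", "median", "p75", "max",
                                                 "out_of_range"])

    datasets = {"activity": activity, "prescriptions": prescriptions,
                "laboratory": laboratory}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in datasets.items():
            frame.to_csv(out / f"{name}.csv", index=False)
            (out / f"{name}.json").write_text(
                json.dumps(frame.to_dict("records"), indent=1), encoding="utf-8")
    return datasets
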