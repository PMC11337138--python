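"""Semantic-mapping pass: build the mapping ledger from staging tables.

Classifies every distinct source vocabulary item into its difficulty level,
registers local concepts (ids > 2,000,000,000) for the manually mapped
level-3 items, replays the two independent annotators' choices from the
bundled worksheet (``data/mappings.csv``) through the reconciliation logic,
resolves drug codes through the two-hop CIP → ATC → RxNorm chain, and
links every consensus to its standard concept with a ``Maps to``
relationship.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .extract import StagingStore
from .vocabulary import (ConceptStore, KappaResult, MappingItem, MappingLedger,
                         SourceItem, classify_difficulty, map_drug, normalize_label)

_DATA_DIR = Path(__file__).parent / "data"

VISIT_CONCEPT_ID = 38004247  # Ambulatory Primary Care Clinic/Center


def load_bundled_annotations() -> dict[tuple[str, str], dict]:
    """The dual-annotator worksheet keyed by (feature, normalized label)."""
    out = {}
    with open(_DATA_DIR / "mappings.csv", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out[(row["feature"], row["normalized_label"])] = {
                "target_vocabulary": row["target_vocabulary"],
                "domain": row["domain"],
                "annotator_a": int(row["annotator_a"]),
                "annotator_b": int(row["annotator_b"]),
                "adjudicator": int(row["adjudicator"]) if row["adjudicator"] else None,
            }
    return out


def _value_counts(series: pd.Series) -> dict[str, int]:
    return {str(k): int(v) for k, v in series.dropna().value_counts().items()}


def build_ledger(staging: StagingStore, store: ConceptStore,
                 annotations: dict | None = None) -> tuple[MappingLedger, KappaResult | None]:
    """Run the full semantic-mapping pass.

    Returns the populated ledger and the inter-annotator κ over the
    dual-annotated (manual, level-3) items. The store is mutated: local
    concepts are registered and ``Maps to`` links appended.
    """
    if annotations is None:
        annotations = load_bundled_annotations()
    ledger = MappingLedger()

    def add_manual(feature: str, raw: str, n_records: int, level: int = 3) -> None:
        normalized = normalize_label(raw)
        item = ledger.add(MappingItem(
            feature=feature, raw_label=raw, normalized_label=normalized,
            source_vocabulary="local",
            target_vocabulary=annotations.get((feature, normalized), {}).get(
                "target_vocabulary", ""),
            difficulty_level=level, n_records=n_records))
        ann = annotations.get((feature, normalized))
        if ann is None or item.consensus is not None:
            return
        if item.local_concept_id is None:
            item.local_concept_id = store.register_local_concept(
                normalized, "local", ann["domain"]).concept_id
        ledger.record_consensus(feature, normalized, ann["annotator_a"],
                                ann["annotator_b"], ann["adjudicator"], store=store)

    # patient characteristics: sex (level 3 → Gender)
    for raw, n in _value_counts(staging.patients["sex"]).items():
        add_manual("sex", raw, n)

    # structured examination variables (level 3 → SNOMED)
    for raw, n in _value_counts(staging.biometrics["variable"]).items():
        add_manual("biometric", raw, n)

    # laboratory variables (level 3 → LOINC), heterogeneous per laboratory
    for raw, n in _value_counts(staging.lab_results["variable"]).items():
        add_manual("laboratory", raw, n)

    # measurement units (level 3 → UCUM)
    units = pd.concat([staging.biometrics["unit"], staging.lab_results["unit"]])
    for raw, n in _value_counts(units).items():
        add_manual("unit", raw, n)

    # ICD-10-coded medical histories (level 1 when the code is standard)
    coded = staging.histories[staging.histories["coded"]]
    for code, n in _value_counts(coded["code"]).items():
        level = classify_difficulty(SourceItem(code, "ICD10", code=code), store)
        concept = store.get_by_code("ICD10", code)
        ledger.add(MappingItem(
            feature="medical_history", raw_label=code,
            normalized_label=normalize_label(code), source_vocabulary="ICD10",
            target_vocabulary="ICD10", difficulty_level=level, n_records=n,
            consensus=concept.concept_id if concept and level == 1 else None,
            source_concept_id=concept.concept_id if concept else None))

    # drugs: CIP (level 3, first hop) and the ATC codes reached (level 2)
    atc_records: dict[str, int] = {}
    for cip, n in _value_counts(staging.prescriptions["cip_code"]).items():
        mapping = map_drug(cip, store)
        level = classify_difficulty(SourceItem(cip, "CIP", code=cip), store)
        ledger.add(MappingItem(
            feature="drug", raw_label=cip, normalized_label=cip,
            source_vocabulary="CIP", target_vocabulary="ATC",
            difficulty_level=level, n_records=n,
            consensus=mapping.atc_concept_id,
            source_concept_id=mapping.cip_concept_id))
        if mapping.atc_concept_id is not None:
            atc = store.get(mapping.atc_concept_id)
            atc_records[atc.concept_code] = atc_records.get(atc.concept_code, 0) + n
    for atc_code, n in sorted(atc_records.items()):
        concept = store.get_by_code("ATC", atc_code)
        level = classify_difficulty(SourceItem(atc_code, "ATC", code=atc_code), store)
        targets = store.related(concept.concept_id, "ATC to RxNorm")
        ledger.add(MappingItem(
            feature="drug_atc", raw_label=atc_code, normalized_label=atc_code,
            source_vocabulary="ATC", target_vocabulary="RxNorm",
            difficulty_level=level, n_records=n,
            consensus=sorted(targets)[0] if targets else None,
            source_concept_id=concept.concept_id))

    # visits (level 1: the standard ambulatory primary-care visit concept)
    if len(staging.consultations):
        ledger.add(MappingItem(
            feature="visit", raw_label="consultation", normalized_label="consultation",
            source_vocabulary="local", target_vocabulary="Visit", difficulty_level=1,
            n_records=len(staging.consultations), consensus=VISIT_CONCEPT_ID))

    # free-text provenance classes (level 4 — out of mapping scope)
    free = _value_counts(staging.notes["provenance"])
    n_free_hist = int((~staging.histories["coded"]).sum())
    if n_free_hist:
        free["history"] = free.get("history", 0) + n_free_hist
    for provenance, n in sorted(free.items()):
        ledger.add(MappingItem(
            feature="free_text", raw_label=provenance, normalized_label=provenance,
            source_vocabulary="local", target_vocabulary="",
            difficulty_level=4, n_records=n))

    annotated = [i for i in ledger.items
                 if i.annotator_a is not None and i.annotator_b is not None]
    kappa = ledger.kappa() if annotated else None
    return ledger, kappa
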