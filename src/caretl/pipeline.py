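"""End-to-end orchestration: generate → extract → map → build → load → assess.

Convenience layer used by the CLI, the integration tests and the
reproduction script; every stage remains individually callable.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path

from . import cdm_store, mapping, quality, validate_report
from .cdm_transform import CdmTables, EraConfig, PlausibilityRanges, build_cdm
from .extract import StagingStore, extract_all
from .synthetic_source import (GeneratorConfig, GroundTruthManifest, SourceExport,
                               generate_export, inject_defects)
from .vocabulary import ConceptStore, KappaResult, MappingLedger, bundled_store


@dataclass
class PipelineResult:
    export: SourceExport
    manifest: GroundTruthManifest
    staging: StagingStore
    store: ConceptStore
    ledger: MappingLedger
    kappa: KappaResult | None
    cdm: CdmTables
    conn: sqlite3.Connection
    load_report: cdm_store.LoadReport
    quality_results: list[quality.QualityResult]
    quality_summary: dict
    validation: dict | None
    concordance: validate_report.ConcordanceReport | None


def run_pipeline(config: GeneratorConfig,
                 workdir: str | Path | None = None,
                 defects: dict[str, int] | None = None,
                 era_config: EraConfig = EraConfig(),
                 ranges: PlausibilityRanges | None = None,
                 filter_outliers: bool = True,
                 db_path: str | Path | None = None,
                 run_validation: bool = True) -> PipelineResult:
    """Run the whole ETL on a fresh synthetic export.

    When ``workdir`` is given the XML export (and manifest) are written
    there and re-read from disk, exercising the file round-trip; otherwise
    extraction runs on the in-memory documents. ``defects`` (kind → count)
    are injected before extraction — quality builds with defects should
    also pass ``filter_outliers=False`` so injected outliers reach the
    warehouse instead of being filtered by the transform.
    """
    if ranges is None:
        ranges = PlausibilityRanges.default()

    export, manifest = generate_export(config)
    if defects:
        export, manifest = inject_defects(export, defects, seed=config.seed + 1)

    if workdir is not None:
        out = export.write(workdir, manifest)
        staging = extract_all(out)
    else:
        staging = extract_all(export)

    store = bundled_store()
    ledger, kappa = mapping.build_ledger(staging, store)

    cdm = build_cdm(staging, ledger, store, ranges=ranges, era_config=era_config,
                    filter_outliers=filter_outliers)

    conn = cdm_store.connect(db_path)
    cdm_store.create_schema(conn)
    cdm_store.load_concept_store(store, conn)
    load_report = cdm_store.load_cdm(cdm.tables, conn)

    results = quality.run_checks(conn, ranges=ranges)
    summary = quality.summarize_checks(results)

    validation = concordance = None
    if run_validation:
        validation = validate_report.run_validation_queries(
            conn, cutoff_date=ranges.extraction_date)
        concordance = validate_report.compare_to_source(validation, manifest)

    return PipelineResult(export, manifest, staging, store, ledger, kappa, cdm,
                          conn, load_report, results, summary, validation,
                          concordance)
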