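"""Synthetic primary-care EHR export generator.

Emulates the per-patient hierarchical XML export of a French primary-care
EHR: demographics, registration with a family physician, consultations in
four steps (free-text reason, free-text interview, structured biometric
examination, outcome with free-text diagnosis, CIP-coded drug prescriptions,
referrals and vaccination notes), laboratory result sets with
laboratory-specific variable spellings and units, partly ICD-10-coded
medical histories, addresses, external clinical reports and death records.

The generator writes one XML document per patient (schema documented in
``docs/xml_schema.md``, version 1.0) together with a :class:`GroundTruthManifest`
recording the exact counts and per-patient event-date extents actually
written, so every downstream ETL stage can be verified against a known
truth.  Output is byte-identical for identical ``(config, seed)``.

Laboratory vocabulary heterogeneity is deliberate: each simulated laboratory
uses its own spelling and unit notation for the same analyte (e.g.
``creatinine`` vs ``create``), which is what the semantic-mapping stage has
to reconcile.
"""

from __future__ import annotations

import copy
import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from lxml import etree

from .errors import CapacityError, ConfigurationError

SCHEMA_VERSION = "1.0"

_DATA_DIR = Path(__file__).parent / "data"

DEFECT_KINDS = (
    "event_after_death",
    "value_out_of_range",
    "birth_year_implausible",
    "dangling_visit_reference",
    "missing_required_field",
)

#: value used when injecting an implausible birth year
IMPLAUSIBLE_BIRTH_YEAR = 1850


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabAnalyte:
    """One laboratory analyte with its per-laboratory spelling variants."""

    canonical: str
    variants: tuple[tuple[str, str], ...]  # (variable spelling, unit spelling)
    mean: float
    sd: float
    lo: float
    hi: float
    decimals: int = 2


@dataclass(frozen=True)
class BiometricVariable:
    """A structured examination variable entered during step three."""

    canonical: str
    label: str
    unit: str
    mean: float
    sd: float
    lo: float
    hi: float
    per_visit_rate: float
    decimals: int = 1


@dataclass(frozen=True)
class CipEntry:
    """A CIP drug presentation code with its ATC parent class(es)."""

    cip: str
    atc_codes: tuple[str, ...]


def _load_plausibility() -> dict:
    with open(_DATA_DIR / "plausibility.yaml", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def default_lab_catalog() -> tuple[LabAnalyte, ...]:
    """Analyte catalog with spelling/unit heterogeneity across laboratories."""
    p = {m["canonical"]: m for m in _load_plausibility()["measurements"]}

    def rng(c):
        return p[c]["min"], p[c]["max"]

    return (
        LabAnalyte("creatinine", (("creatinine", "mg/dL"), ("create", "mg/dl")),
                   0.9, 0.2, *rng("creatinine")),
        LabAnalyte("potassium", (("Potassium", "mmol/L"), ("3. Potassium (mmol/L):", "mmol/L")),
                   4.2, 0.4, *rng("potassium")),
        LabAnalyte("crp", (("CRP", "mg/L"), ("C-reactive protein", "mg/L")),
                   5.0, 3.0, *rng("crp"), 1),
        LabAnalyte("glucose", (("glucose", "mmol/L"), ("Glycémie", "mmol/L")),
                   5.5, 0.8, *rng("glucose")),
        LabAnalyte("hemoglobin", (("Hémoglobine", "g/dL"), ("hemoglobine", "g/dl")),
                   14.0, 1.5, *rng("hemoglobin"), 1),
        LabAnalyte("sodium", (("Sodium", "mmol/L"), ("sodium", "mmol/L")),
                   140.0, 3.0, *rng("sodium"), 1),
    )


def default_biometric_catalog() -> tuple[BiometricVariable, ...]:
    p = {m["canonical"]: m for m in _load_plausibility()["measurements"]}

    def rng(c):
        return p[c]["min"], p[c]["max"]

    return (
        BiometricVariable("poids", "Poids", "kg", 75, 15, *rng("poids"), 0.15),
        BiometricVariable("taille", "Taille", "cm", 170, 10, *rng("taille"), 0.02),
        BiometricVariable("frequence cardiaque", "Fréquence cardiaque", "bpm",
                          72, 10, *rng("frequence cardiaque"), 0.05),
        BiometricVariable("pa systolique", "PA systolique", "mmHg",
                          128, 15, *rng("pa systolique"), 0.08),
    )


_DEFAULT_ATCS = ("A10BA02", "C09AA05", "N02BE01", "J01CA04", "C10AA05",
                 "R03AC02", "N06AB06", "B01AC06", "J01CR02")


def default_cip_catalog() -> tuple[CipEntry, ...]:
    """20 CIP-13 codes cycling over 9 ATC classes (matching the bundled
    vocabulary fixture)."""
    return tuple(
        CipEntry(f"34009{30000000 + i:08d}", (_DEFAULT_ATCS[i % len(_DEFAULT_ATCS)],))
        for i in range(20)
    )


_DEFAULT_ICD10 = ("E11", "I10", "J45", "E78", "F41", "M54", "K21", "E03", "G43", "N39")
_TOWNS = ("Wattrelos", "Roubaix", "Tourcoing", "Lille", "Leers", "Lys-lez-Lannoy")

# template snippets for free-text fields; they exist to be stored in NOTE,
# not to be clinically realistic
_REASONS = ("Douleur abdominale", "Fievre depuis deux jours", "Toux persistante",
            "Renouvellement ordonnance", "Douleur lombaire", "Certificat sportif",
            "Controle tension", "Fatigue inhabituelle")
_INTERVIEWS = ("Pas de signe de gravite", "Douleur cotee 4/10", "Appetit conserve",
               "Sommeil perturbe", "Antecedents familiaux notes", "Examen sans anomalie")
_DIAGNOSES = ("Gastro-enterite aigue", "Syndrome grippal", "Lombalgie commune",
              "Hypertension equilibree", "Bronchite aigue", "Anxiete reactionnelle")
_REFERRALS = ("Adresse au cardiologue", "Adresse au dermatologue", "Bilan radiologique demande")
_VACCINATIONS = ("Vaccin antigrippal effectue", "Rappel DTP effectue")
_SUPPLEMENTARY = ("Conseils hygieno-dietetiques donnes", "A revoir dans un mois",
                  "Arret de travail 3 jours")
_FREE_HISTORIES = ("diabetique depuis 2004", "appendicectomie dans l'enfance",
                   "tabagisme sevre en 2015", "allergie penicilline")
_REPORTS = ("Compte rendu de consultation cardiologique: examen normal.",
            "Compte rendu ophtalmologique: fond d'oeil sans anomalie.",
            "Courrier du rhumatologue: poursuite du traitement.")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic export.

    Default rates are calibrated on the volume ratios of a real 20-year
    primary-care warehouse (about 32 consultations and 50 prescriptions per
    patient over the period, 2.3% deceased patients, 3.6% of medical-history
    items ICD-10-coded, 8 family physicians).
    """

    n_patients: int = 100
    date_range: tuple[dt.date, dt.date] = (dt.date(2013, 1, 1), dt.date(2021, 6, 30))
    n_physicians: int = 8
    mean_visits_per_patient: float = 32.2
    lab_catalog: tuple[LabAnalyte, ...] = field(default_factory=default_lab_catalog)
    biometric_catalog: tuple[BiometricVariable, ...] = field(default_factory=default_biometric_catalog)
    cip_catalog: tuple[CipEntry, ...] = field(default_factory=default_cip_catalog)
    icd10_codes: tuple[str, ...] = _DEFAULT_ICD10
    icd10_history_rate: float = 0.036
    death_rate: float = 0.023
    mean_prescriptions_per_visit: float = 1.56
    mean_lab_panels_per_patient: float = 8.0
    mean_results_per_panel: float = 6.0
    mean_history_items_per_patient: float = 2.0
    mean_clinical_reports_per_patient: float = 1.0
    diagnosis_rate: float = 0.6
    referral_rate: float = 0.1
    vaccination_rate: float = 0.05
    supplementary_rate: float = 0.2
    n_laboratories: int = 3
    lab_consultation_ref_rate: float = 0.3
    lab_high_potassium_threshold: float = 5.0
    seed: int = 0

    @property
    def lab_vocabulary_variants(self) -> dict[str, list[tuple[str, str]]]:
        return {a.canonical: list(a.variants) for a in self.lab_catalog}

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.date_range[0] >= self.date_range[1]:
            raise ConfigurationError("date_range start must precede end")
        if self.n_physicians < 1:
            raise ConfigurationError("n_physicians must be >= 1")
        if self.mean_visits_per_patient < 0:
            raise ConfigurationError("mean_visits_per_patient must be >= 0")
        for entry in self.cip_catalog:
            if not entry.atc_codes:
                raise ConfigurationError(f"cip_catalog entry {entry.cip} has no ATC parent")
        for name in ("icd10_history_rate", "death_rate", "diagnosis_rate", "referral_rate",
                     "vaccination_rate", "supplementary_rate", "lab_consultation_ref_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be within [0, 1]")
        for a in self.lab_catalog:
            if a.lo >= a.hi:
                raise ConfigurationError(f"lab_catalog range invalid for {a.canonical}")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass
class DefectRecord:
    kind: str
    patient_ref: str
    detail: str


@dataclass
class GroundTruthManifest:
    """Exact truth about what was written to the export.

    ``source_truth`` holds the values a clinician would read directly off the
    source software, used as the oracle for the source-vs-warehouse
    validation queries.
    """

    true_n_patients: int
    true_n_consultations: int
    true_n_prescriptions: int
    true_n_lab_results: int
    true_n_biometrics: int
    true_n_deaths: int
    true_n_coded_histories: int
    true_n_free_text_items: int
    per_physician_patient_counts: dict[str, int]
    per_patient_event_date_extents: dict[str, tuple[str, str]]
    source_truth: dict
    injected_defects: list[DefectRecord] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        payload["injected_defects"] = [DefectRecord(**d) for d in payload["injected_defects"]]
        payload["per_patient_event_date_extents"] = {
            k: tuple(v) for k, v in payload["per_patient_event_date_extents"].items()
        }
        return cls(**payload)


# ---------------------------------------------------------------------------
# export container
# ---------------------------------------------------------------------------

class SourceExport:
    """In-memory per-patient XML documents, written one file per patient."""

    def __init__(self, documents: dict[str, etree._Element], config: GeneratorConfig):
        self.documents = documents
        self.config = config

    @property
    def patient_ids(self) -> list[str]:
        return list(self.documents)

    def to_bytes(self, patient_id: str) -> bytes:
        return etree.tostring(self.documents[patient_id], pretty_print=True,
                              xml_declaration=True, encoding="UTF-8")

    def write(self, out_dir: str | Path, manifest: GroundTruthManifest | None = None) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for pid in self.documents:
            (out / f"{pid}.xml").write_bytes(self.to_bytes(pid))
        if manifest is not None:
            manifest.to_json(out / "manifest.json")
        return out

    def copy(self) -> "SourceExport":
        return SourceExport({pid: copy.deepcopy(el) for pid, el in self.documents.items()},
                            self.config)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _iso(d: dt.date) -> str:
    return d.isoformat()


def _rand_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _clipped_value(rng: np.random.Generator, mean, sd, lo, hi, decimals) -> float:
    # draws are clipped into the plausible range: the generator emits only
    # plausible values, so injected defects are the sole source of outliers
    v = float(np.clip(rng.normal(mean, sd), lo, hi))
    return round(v, decimals)


def _sub(parent, tag, text=None, **attrs):
    el = etree.SubElement(parent, tag)
    for k, v in attrs.items():
        el.set(k.replace("_", "-"), str(v))
    if text is not None:
        el.text = text
    return el


def _generate_patient(rng: np.random.Generator, cfg: GeneratorConfig, index: int) -> etree._Element:
    start, end = cfg.date_range
    pid = f"W{100000 + index}"
    root = etree.Element("patient", id=pid)
    root.set("schema-version", SCHEMA_VERSION)

    sex = str(rng.choice(["M", "F"]))
    yob = int(rng.integers(1920, 2010))
    town = str(rng.choice(_TOWNS))
    demo = _sub(root, "demographics")
    _sub(demo, "sex", sex)
    _sub(demo, "year-of-birth", str(yob))
    _sub(demo, "town", town)
    _sub(demo, "country", "FR")

    physician = f"dr-{int(rng.integers(1, cfg.n_physicians + 1)):02d}"

    addresses = _sub(root, "addresses")
    _sub(addresses, "address", town=town, zip="59150",
         line=f"{int(rng.integers(1, 120))} rue de la Mairie")

    # consultations
    n_visits = int(rng.poisson(cfg.mean_visits_per_patient))
    span = (end - start).days
    offsets = sorted(int(o) for o in rng.integers(0, span + 1, size=n_visits))
    visit_dates = [start + dt.timedelta(days=o) for o in offsets]
    event_dates: list[dt.date] = list(visit_dates)

    reg_date = visit_dates[0] if visit_dates else _rand_date(rng, start, end)
    _sub(root, "registration", physician=physician, date=_iso(reg_date))

    consultations = _sub(root, "consultations")
    consult_ids: list[str] = []
    for j, date in enumerate(visit_dates):
        cid = f"{pid}-c{j:04d}"
        consult_ids.append(cid)
        c = _sub(consultations, "consultation", id=cid, date=_iso(date))
        _sub(c, "reason", str(rng.choice(_REASONS)))
        _sub(c, "interview", str(rng.choice(_INTERVIEWS)))
        exam = _sub(c, "examination")
        for b in cfg.biometric_catalog:
            if rng.random() < b.per_visit_rate:
                _sub(exam, "biometric", variable=b.label, unit=b.unit,
                     value=str(_clipped_value(rng, b.mean, b.sd, b.lo, b.hi, b.decimals)))
        outcome = _sub(c, "outcome")
        if rng.random() < cfg.diagnosis_rate:
            _sub(outcome, "diagnosis", str(rng.choice(_DIAGNOSES)))
        for _ in range(int(rng.poisson(cfg.mean_prescriptions_per_visit))):
            entry = cfg.cip_catalog[int(rng.integers(0, len(cfg.cip_catalog)))]
            _sub(outcome, "prescription", cip=entry.cip,
                 days_supply=str(int(rng.choice([7, 14, 28, 30, 90]))),
                 quantity=str(int(rng.integers(1, 4))),
                 refills=str(int(rng.integers(0, 3))))
        if rng.random() < cfg.referral_rate:
            _sub(outcome, "referral", str(rng.choice(_REFERRALS)))
        if rng.random() < cfg.vaccination_rate:
            _sub(outcome, "vaccination", str(rng.choice(_VACCINATIONS)))
        if rng.random() < cfg.supplementary_rate:
            _sub(outcome, "supplementary", str(rng.choice(_SUPPLEMENTARY)))

    # laboratory result sets: each laboratory consistently uses its own
    # spelling variant for every analyte
    labs = _sub(root, "lab-results")
    n_panels = int(rng.poisson(cfg.mean_lab_panels_per_patient))
    for k in range(n_panels):
        lab_no = int(rng.integers(1, cfg.n_laboratories + 1))
        date = _rand_date(rng, start, end)
        event_dates.append(date)
        rs = _sub(labs, "result-set", id=f"{pid}-l{k:04d}",
                  laboratory=f"lab-{lab_no}", date=_iso(date))
        if consult_ids and rng.random() < cfg.lab_consultation_ref_rate:
            rs.set("consultation-ref", consult_ids[int(rng.integers(0, len(consult_ids)))])
        n_results = 1 + int(rng.poisson(max(cfg.mean_results_per_panel - 1, 0)))
        n_results = min(n_results, len(cfg.lab_catalog))
        chosen = rng.choice(len(cfg.lab_catalog), size=n_results, replace=False)
        for ai in sorted(int(a) for a in chosen):
            a = cfg.lab_catalog[ai]
            label, unit = a.variants[(lab_no - 1) % len(a.variants)]
            _sub(rs, "result", variable=label, unit=unit,
                 value=str(_clipped_value(rng, a.mean, a.sd, a.lo, a.hi, a.decimals)))

    # medical history: a small fraction ICD-10-coded, the rest free text
    history = _sub(root, "medical-history")
    for _ in range(int(rng.poisson(cfg.mean_history_items_per_patient))):
        date = _rand_date(rng, start, end)
        event_dates.append(date)
        if rng.random() < cfg.icd10_history_rate:
            _sub(history, "history", coded="true", date=_iso(date),
                 code=str(rng.choice(cfg.icd10_codes)))
        else:
            _sub(history, "history", str(rng.choice(_FREE_HISTORIES)),
                 coded="false", date=_iso(date))

    # clinical reports from external specialists
    reports = _sub(root, "clinical-reports")
    for _ in range(int(rng.poisson(cfg.mean_clinical_reports_per_patient))):
        date = _rand_date(rng, start, end)
        event_dates.append(date)
        _sub(reports, "report", str(rng.choice(_REPORTS)), date=_iso(date))

    if rng.random() < cfg.death_rate:
        last = max(event_dates) if event_dates else _rand_date(rng, start, end)
        death = min(last + dt.timedelta(days=int(rng.integers(0, 181))), end)
        death = max(death, last)  # death never precedes the last recorded event
        _sub(root, "death", date=_iso(death))

    return root


def generate_export(config: GeneratorConfig) -> tuple[SourceExport, GroundTruthManifest]:
    """Generate the per-patient XML export and its ground-truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    documents = {}
    for i in range(config.n_patients):
        root = _generate_patient(rng, config, i)
        documents[root.get("id")] = root
    export = SourceExport(documents, config)
    return export, scan_manifest(export)


# ---------------------------------------------------------------------------
# manifest scan (recount over the XML — consistency holds by construction)
# ---------------------------------------------------------------------------

def scan_manifest(export: SourceExport,
                  defects: list[DefectRecord] | None = None) -> GroundTruthManifest:
    """Recount the export content into a manifest.

    Used both at generation time and after defect injection, so manifest
    counts always equal a direct recount over the written XML.
    """
    cfg = export.config
    cip_to_atc = {e.cip: e.atc_codes for e in cfg.cip_catalog}
    label_to_canonical = {}
    for a in cfg.lab_catalog:
        for label, _unit in a.variants:
            label_to_canonical[label] = a.canonical

    n_consult = n_rx = n_lab = n_bio = n_death = n_coded = n_free = 0
    per_phys: dict[str, int] = {}
    extents: dict[str, tuple[str, str]] = {}
    atc_patients: dict[str, set] = {}
    high_k_patients: set = set()

    for pid, root in export.documents.items():
        reg = root.find("registration")
        if reg is not None:
            per_phys[reg.get("physician")] = per_phys.get(reg.get("physician"), 0) + 1
        dates: list[str] = []
        for c in root.iterfind("consultations/consultation"):
            n_consult += 1
            dates.append(c.get("date"))
            for el in c.iterfind("examination/biometric"):
                n_bio += 1
            for el in c.iterfind("outcome/prescription"):
                n_rx += 1
                for atc in cip_to_atc.get(el.get("cip"), ()):
                    atc_patients.setdefault(atc, set()).add(pid)
            for tag in ("reason", "interview"):
                if c.find(tag) is not None:
                    n_free += 1
            for tag in ("diagnosis", "referral", "vaccination", "supplementary"):
                for _el in c.iterfind(f"outcome/{tag}"):
                    n_free += 1
        for rs in root.iterfind("lab-results/result-set"):
            dates.append(rs.get("date"))
            for r in rs.iterfind("result"):
                n_lab += 1
                canonical = label_to_canonical.get(r.get("variable"))
                if canonical == "potassium":
                    try:
                        if float(r.get("value")) > cfg.lab_high_potassium_threshold:
                            high_k_patients.add(pid)
                    except (TypeError, ValueError):
                        pass
        for h in root.iterfind("medical-history/history"):
            dates.append(h.get("date"))
            if h.get("coded") == "true":
                n_coded += 1
            else:
                n_free += 1
        for r in root.iterfind("clinical-reports/report"):
            dates.append(r.get("date"))
            n_free += 1
        if root.find("death") is not None:
            n_death += 1
        dated = [d for d in dates if d]
        if dated:
            extents[pid] = (min(dated), max(dated))

    truth = {
        "patients_per_physician": dict(sorted(per_phys.items())),
        "n_consultations": n_consult,
        "patients_on_atc": {k: len(v) for k, v in sorted(atc_patients.items())},
        "high_potassium": {"threshold": cfg.lab_high_potassium_threshold,
                           "n_patients": len(high_k_patients)},
    }
    return GroundTruthManifest(
        true_n_patients=len(export.documents),
        true_n_consultations=n_consult,
        true_n_prescriptions=n_rx,
        true_n_lab_results=n_lab,
        true_n_biometrics=n_bio,
        true_n_deaths=n_death,
        true_n_coded_histories=n_coded,
        true_n_free_text_items=n_free,
        per_physician_patient_counts=per_phys,
        per_patient_event_date_extents=extents,
        source_truth=truth,
        injected_defects=list(defects or []),
    )


# ---------------------------------------------------------------------------
# defect injection
# ---------------------------------------------------------------------------

def inject_defects(export: SourceExport, spec: dict[str, int],
                   seed: int) -> tuple[SourceExport, GroundTruthManifest]:
    """Inject known data defects into a copy of the export.

    ``spec`` maps defect kinds (a closed set, :data:`DEFECT_KINDS`) to
    requested counts.  The returned manifest enumerates every injected
    defect with its location; all counts are recomputed from the mutated
    documents so manifest-export consistency is preserved.
    """
    for kind in spec:
        if kind not in DEFECT_KINDS:
            raise ConfigurationError(f"unknown defect kind: {kind}")
    mutated = export.copy()
    if not spec:
        return mutated, scan_manifest(mutated)

    rng = np.random.default_rng(seed)
    cfg = export.config
    defects: list[DefectRecord] = []
    range_by_label = {b.label: (b.lo, b.hi) for b in cfg.biometric_catalog}
    for a in cfg.lab_catalog:
        for label, _unit in a.variants:
            range_by_label[label] = (a.lo, a.hi)

    def pick(kind: str, candidates: list) -> list:
        n = spec.get(kind, 0)
        if n > len(candidates):
            raise CapacityError(
                f"{kind}: requested {n} defects but only {len(candidates)} candidates")
        idx = rng.choice(len(candidates), size=n, replace=False) if n else []
        return [candidates[int(i)] for i in idx]

    docs = mutated.documents

    if "event_after_death" in spec:
        candidates = []
        for pid, root in docs.items():
            death = root.find("death")
            if death is None:
                continue
            for c in root.iterfind("consultations/consultation"):
                candidates.append((pid, c, death.get("date")))
        for pid, c, death_date in pick("event_after_death", candidates):
            new = dt.date.fromisoformat(death_date) + dt.timedelta(days=30)
            c.set("date", new.isoformat())
            defects.append(DefectRecord("event_after_death", pid,
                                        f"consultation {c.get('id')} moved to {new.isoformat()}"))

    if "value_out_of_range" in spec:
        candidates = []
        for pid, root in docs.items():
            for el in root.iterfind("consultations/consultation/examination/biometric"):
                if el.get("variable") in range_by_label:
                    candidates.append((pid, el))
            for el in root.iterfind("lab-results/result-set/result"):
                if el.get("variable") in range_by_label:
                    candidates.append((pid, el))
        for pid, el in pick("value_out_of_range", candidates):
            lo, hi = range_by_label[el.get("variable")]
            el.set("value", str(round(hi * 10, 2)))
            defects.append(DefectRecord("value_out_of_range", pid,
                                        f"{el.get('variable')} set to {el.get('value')} "
                                        f"(plausible range [{lo}, {hi}])"))

    if "birth_year_implausible" in spec:
        candidates = [(pid, root.find("demographics/year-of-birth"))
                      for pid, root in docs.items()
                      if root.find("demographics/year-of-birth") is not None]
        for pid, el in pick("birth_year_implausible", candidates):
            el.text = str(IMPLAUSIBLE_BIRTH_YEAR)
            defects.append(DefectRecord("birth_year_implausible", pid,
                                        f"year-of-birth set to {IMPLAUSIBLE_BIRTH_YEAR}"))

    if "dangling_visit_reference" in spec:
        candidates = [(pid, rs) for pid, root in docs.items()
                      for rs in root.iterfind("lab-results/result-set")]
        for i, (pid, rs) in enumerate(pick("dangling_visit_reference", candidates)):
            rs.set("consultation-ref", f"missing-c{i:04d}")
            defects.append(DefectRecord("dangling_visit_reference", pid,
                                        f"result-set {rs.get('id')} references missing-c{i:04d}"))

    if "missing_required_field" in spec:
        candidates = [(pid, root.find("demographics"))
                      for pid, root in docs.items()
                      if root.find("demographics/sex") is not None]
        for pid, demo in pick("missing_required_field", candidates):
            demo.remove(demo.find("sex"))
            defects.append(DefectRecord("missing_required_field", pid,
                                        "demographics/sex removed"))

    return mutated, scan_manifest(mutated, defects)
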