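"""Standard and local vocabularies, semantic mapping and agreement metrics.

The semantic-mapping workflow mirrors common OHDSI practice: local vocabulary
items are classified into four difficulty levels (1 — already a standard
concept; 2 — a standard mapping already exists; 3 — structured but needing
manual mapping; 4 — free text, out of mapping scope), labels are normalized
before matching, drug codes are mapped in two hops (CIP → ATC → RxNorm),
manual mappings are produced by two independent annotators whose agreement is
quantified with Cohen's κ and reconciled by a third expert, and newly created
local concepts receive identifiers above 2,000,000,000 with a ``Maps to``
relationship to their standard counterpart.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from difflib import SequenceMatcher
from pathlib import Path
from collections import Counter

import pandas as pd

from .errors import InputError, IntegrityError

_DATA_DIR = Path(__file__).parent / "data"

LOCAL_ID_FLOOR = 2_000_000_000

#: relationship ids that mean "a standard mapping already exists" (level 2);
#: "CIP to ATC" is deliberately excluded — those links are the site's own
#: manual-mapping artifact, so CIP items remain level 3
LEVEL2_RELATIONSHIPS = ("Maps to", "ATC to RxNorm")

ALLOWED_RELATIONSHIPS = ("Maps to", "CIP to ATC", "ATC to RxNorm", "RxNorm has ingredient")


@dataclass(frozen=True)
class Concept:
    concept_id: int
    name: str
    vocabulary_id: str
    concept_code: str
    is_standard: bool
    domain: str


@dataclass(frozen=True)
class ConceptRelationship:
    source_concept_id: int
    target_concept_id: int
    relationship: str


class ConceptStore:
    """In-memory CONCEPT / CONCEPT_RELATIONSHIP / VOCABULARY store.

    Enforces referential integrity, concept-id uniqueness, the local-id
    partition (local ids strictly above 2,000,000,000) and the rule that
    ``Maps to`` always targets a standard concept.
    """

    def __init__(self) -> None:
        self._by_id: dict[int, Concept] = {}
        self._by_code: dict[tuple[str, str], Concept] = {}
        self._by_local_key: dict[tuple[str, str, str], Concept] = {}
        self._rels: dict[tuple[int, str], list[int]] = {}
        self._all_rels: list[ConceptRelationship] = []
        self.vocabularies: dict[str, str] = {}
        self._next_local = LOCAL_ID_FLOOR + 1

    # -- construction -------------------------------------------------------

    def add_vocabulary(self, vocabulary_id: str, name: str) -> None:
        self.vocabularies[vocabulary_id] = name

    def add_concept(self, concept: Concept) -> Concept:
        if concept.concept_id in self._by_id:
            raise IntegrityError(f"duplicate concept_id {concept.concept_id}")
        if concept.concept_id > LOCAL_ID_FLOOR and concept.vocabulary_id != "local":
            raise IntegrityError(
                f"concept_id {concept.concept_id} is in the local id range but "
                f"belongs to vocabulary {concept.vocabulary_id!r}")
        if concept.vocabulary_id == "local" and not concept.concept_id > LOCAL_ID_FLOOR:
            raise IntegrityError(
                f"local concept {concept.concept_id} must have id > {LOCAL_ID_FLOOR}")
        self._by_id[concept.concept_id] = concept
        self._by_code[(concept.vocabulary_id, concept.concept_code)] = concept
        if concept.concept_id >= self._next_local:
            self._next_local = concept.concept_id + 1
        return concept

    def add_relationship(self, source_id: int, target_id: int, relationship: str) -> None:
        if relationship not in ALLOWED_RELATIONSHIPS:
            raise IntegrityError(f"unknown relationship id {relationship!r}")
        missing = [i for i in (source_id, target_id) if i not in self._by_id]
        if missing:
            raise IntegrityError(f"relationship endpoint(s) not in store: {missing}")
        if relationship == "Maps to" and not self._by_id[target_id].is_standard:
            raise IntegrityError(
                f"'Maps to' target {target_id} is not a standard concept")
        self._rels.setdefault((source_id, relationship), []).append(target_id)
        self._all_rels.append(ConceptRelationship(source_id, target_id, relationship))

    def register_local_concept(self, label: str, vocabulary: str, domain: str) -> Concept:
        """Register (idempotently) a local concept with id > 2,000,000,000."""
        if not label:
            raise InputError("cannot register a local concept with an empty label")
        key = (label, vocabulary, domain)
        if key in self._by_local_key:
            return self._by_local_key[key]
        concept = Concept(self._next_local, label, "local", label, False, domain)
        self._next_local += 1
        self._by_id[concept.concept_id] = concept
        self._by_local_key[key] = concept
        return concept

    # -- lookup -------------------------------------------------------------

    def get(self, concept_id: int) -> Concept | None:
        return self._by_id.get(concept_id)

    def get_by_code(self, vocabulary_id: str, code: str) -> Concept | None:
        return self._by_code.get((vocabulary_id, code))

    def related(self, concept_id: int, relationship: str) -> list[int]:
        return list(self._rels.get((concept_id, relationship), []))

    @property
    def concepts(self) -> list[Concept]:
        return list(self._by_id.values())

    @property
    def relationships(self) -> list[ConceptRelationship]:
        return list(self._all_rels)

    @property
    def n_concepts(self) -> int:
        return len(self._by_id)

    @property
    def n_relationships(self) -> int:
        return len(self._all_rels)

    def local_concepts(self) -> list[Concept]:
        return [c for c in self._by_id.values() if c.concept_id > LOCAL_ID_FLOOR]

    def to_frames(self) -> dict[str, pd.DataFrame]:
        concept = pd.DataFrame(
            [(c.concept_id, c.name, c.domain, c.vocabulary_id, c.concept_code,
              "S" if c.is_standard else "") for c in self._by_id.values()],
            columns=["concept_id", "concept_name", "domain_id", "vocabulary_id",
                     "concept_code", "standard_concept"])
        rel = pd.DataFrame(
            [(r.source_concept_id, r.target_concept_id, r.relationship)
             for r in self._all_rels],
            columns=["concept_id_1", "concept_id_2", "relationship_id"])
        vocab = pd.DataFrame(sorted(self.vocabularies.items()),
                             columns=["vocabulary_id", "vocabulary_name"])
        return {"CONCEPT": concept, "CONCEPT_RELATIONSHIP": rel, "VOCABULARY": vocab}


def load_vocabulary_fixture(directory: str | Path) -> ConceptStore:
    """Load CONCEPT/CONCEPT_RELATIONSHIP/VOCABULARY CSVs into a validated store."""
    directory = Path(directory)
    concept = pd.read_csv(directory / "CONCEPT.csv", keep_default_na=False,
                          dtype={"concept_code": str})
    rel = pd.read_csv(directory / "CONCEPT_RELATIONSHIP.csv", keep_default_na=False)
    vocab = pd.read_csv(directory / "VOCABULARY.csv", keep_default_na=False)

    store = ConceptStore()
    for row in vocab.itertuples(index=False):
        store.add_vocabulary(row.vocabulary_id, row.vocabulary_name)
    for row in concept.itertuples(index=False):
        if row.vocabulary_id not in store.vocabularies:
            raise IntegrityError(f"concept {row.concept_id} references undeclared "
                                 f"vocabulary {row.vocabulary_id!r}")
        store.add_concept(Concept(int(row.concept_id), row.concept_name,
                                  row.vocabulary_id, str(row.concept_code),
                                  row.standard_concept == "S", row.domain_id))
    dangling = []
    for row in rel.itertuples(index=False):
        try:
            store.add_relationship(int(row.concept_id_1), int(row.concept_id_2),
                                   row.relationship_id)
        except IntegrityError as exc:
            dangling.append(str(exc))
    if dangling:
        raise IntegrityError("invalid relationships: " + "; ".join(dangling))
    return store


def bundled_store() -> ConceptStore:
    """The packaged synthetic vocabulary fixture."""
    return load_vocabulary_fixture(_DATA_DIR)


# ---------------------------------------------------------------------------
# label normalization
# ---------------------------------------------------------------------------

def load_default_stopwords() -> set[str]:
    return {line.strip() for line in
            (_DATA_DIR / "stopwords_fr.txt").read_text(encoding="utf-8").splitlines()
            if line.strip()}

def load_default_abbreviations() -> dict[str, str]:
    with open(_DATA_DIR / "abbreviations.csv", encoding="utf-8", newline="") as fh:
        return {row["abbreviation"]: row["expansion"] for row in csv.DictReader(fh)}


_LEADING_NUMBER = re.compile(r"^\s*\d+\s*[.)\-:]*\s+")
_SPECIALS = re.compile(r"[^\w\s-]")
_STRAY_HYPHEN = re.compile(r"(?<!\w)-|-(?!\w)")


def normalize_label(raw: str, abbreviations: dict[str, str] | None = None,
                    stopwords: set[str] | None = None) -> str:
    """Canonicalize a source label for matching and grouping.

    Rule order: strip accents; strip a leading chapter/line number; replace
    punctuation and special characters with spaces (keeping intra-word
    hyphens); expand whole-token abbreviations; case-fold; drop stopwords;
    collapse whitespace. Idempotent; an empty result is allowed.
    """
    if raw is None:
        raise InputError("normalize_label: raw label is None")
    if abbreviations is None:
        abbreviations = load_default_abbreviations()
    if stopwords is None:
        stopwords = load_default_stopwords()

    expand = {k.casefold(): v for k, v in abbreviations.items()}
    drop = {s.casefold() for s in stopwords}

    def once(text: str) -> str:
        text = unicodedata.normalize("NFKD", text)
        text = "".join(ch for ch in text if not unicodedata.combining(ch))
        text = _LEADING_NUMBER.sub("", text)
        text = _SPECIALS.sub(" ", text)
        text = _STRAY_HYPHEN.sub(" ", text)
        tokens = [expand.get(t.casefold(), t) for t in text.split()]
        text = " ".join(tokens).casefold()
        return " ".join(t for t in text.split() if t not in drop)

    # the rule sequence is applied to a fixpoint (unicode compatibility
    # folding can surface new leading digits), guaranteeing idempotence
    text = str(raw)
    for _ in range(5):
        new = once(text)
        if new == text:
            break
        text = new
    return text


def suggest_candidates(label: str, store: ConceptStore, domain: str | None = None,
                       threshold: float = 0.85, k: int = 5) -> list[tuple[Concept, float]]:
    """Ranked fuzzy suggestions for manual (level 3) mapping.

    Proposes candidates whose normalized-name similarity reaches ``threshold``;
    it never auto-accepts — a human annotator decides.
    """
    target = normalize_label(label)
    scored = []
    for c in store.concepts:
        if domain and c.domain != domain:
            continue
        sim = SequenceMatcher(None, target, normalize_label(c.name)).ratio()
        if sim >= threshold:
            scored.append((c, sim))
    scored.sort(key=lambda t: (-t[1], t[0].concept_id))
    return scored[:k]


# ---------------------------------------------------------------------------
# difficulty classification and drug mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceItem:
    """A distinct source vocabulary item awaiting classification."""
    raw_label: str
    source_vocabulary: str
    code: str | None = None
    is_free_text: bool = False


def classify_difficulty(item: SourceItem, store: ConceptStore) -> int:
    """Assign the 4-level mapping difficulty of a source item."""
    if item.is_free_text:
        return 4
    if item.code is not None:
        concept = store.get_by_code(item.source_vocabulary, item.code)
        if concept is not None:
            if concept.is_standard:
                return 1
            if any(store.related(concept.concept_id, r) for r in LEVEL2_RELATIONSHIPS):
                return 2
    return 3


@dataclass(frozen=True)
class DrugMapping:
    cip_code: str
    cip_concept_id: int | None
    atc_concept_id: int | None
    rxnorm_concept_id: int | None
    mapped: bool
    reason: str


_CIP13 = re.compile(r"^\d{13}$")


def map_drug(cip_code: str, store: ConceptStore) -> DrugMapping:
    """Two-hop drug mapping: CIP → ATC → RxNorm standard concept."""
    if not _CIP13.match(str(cip_code)):
        raise InputError(f"malformed CIP code {cip_code!r} (13 digits expected)")
    cip = store.get_by_code("CIP", str(cip_code))
    if cip is None:
        return DrugMapping(cip_code, None, None, None, False, "unknown CIP code")
    atcs = store.related(cip.concept_id, "CIP to ATC")
    if not atcs:
        return DrugMapping(cip_code, cip.concept_id, None, None, False,
                           "missing first hop (no CIP to ATC link)")
    atc_id = sorted(atcs)[0]
    rxs = store.related(atc_id, "ATC to RxNorm")
    if not rxs:
        return DrugMapping(cip_code, cip.concept_id, atc_id, None, False,
                           "missing second hop (no ATC to RxNorm link)")
    rx_id = sorted(rxs)[0]
    return DrugMapping(cip_code, cip.concept_id, atc_id, rx_id, True, "mapped")


# ---------------------------------------------------------------------------
# annotator agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KappaResult:
    p_o: float
    p_e: float
    kappa: float
    n_items: int
    n_disagreements: int


def cohen_kappa(annotations_a, annotations_b) -> KappaResult:
    """Cohen's unweighted κ over two paired label sequences.

    κ = (p_o − p_e) / (1 − p_e) with p_o the observed agreement and p_e the
    chance agreement from the annotators' marginal distributions; κ = 1 when
    both are 1 (degenerate single-category case included).
    """
    a = list(annotations_a)
    b = list(annotations_b)
    if len(a) != len(b):
        raise InputError(f"annotation length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise InputError("cohen_kappa requires at least one item")
    n = len(a)
    p_o = sum(x == y for x, y in zip(a, b)) / n
    ca, cb = Counter(a), Counter(b)
    p_e = sum(ca[k] * cb.get(k, 0) for k in ca) / (n * n)
    if p_e >= 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(p_o, p_e, kappa, n, n - round(p_o * n))


# ---------------------------------------------------------------------------
# mapping ledger
# ---------------------------------------------------------------------------

@dataclass
class MappingItem:
    feature: str
    raw_label: str
    normalized_label: str
    source_vocabulary: str
    target_vocabulary: str
    difficulty_level: int
    annotator_a: int | None = None
    annotator_b: int | None = None
    consensus: int | None = None
    adjudicated: bool = False
    n_records: int = 0
    local_concept_id: int | None = None
    source_concept_id: int | None = None


class MappingLedger:
    """Per-source-item record of the semantic-mapping pass."""

    def __init__(self) -> None:
        self._items: dict[tuple[str, str], MappingItem] = {}

    def key(self, feature: str, normalized_label: str) -> tuple[str, str]:
        return (feature, normalized_label)

    def add(self, item: MappingItem) -> MappingItem:
        if item.difficulty_level not in (1, 2, 3, 4):
            raise InputError(f"difficulty_level must be 1..4, got {item.difficulty_level}")
        if item.difficulty_level == 4 and item.consensus is not None:
            raise IntegrityError("level-4 (free text) items cannot carry a consensus")
        k = self.key(item.feature, item.normalized_label)
        existing = self._items.get(k)
        if existing is not None:
            existing.n_records += item.n_records
            return existing
        self._items[k] = item
        return item

    def get(self, feature: str, normalized_label: str) -> MappingItem | None:
        return self._items.get((feature, normalized_label))

    def lookup(self, feature: str, raw_label: str) -> MappingItem | None:
        return self.get(feature, normalize_label(raw_label))

    @property
    def items(self) -> list[MappingItem]:
        return list(self._items.values())

    def __len__(self) -> int:
        return len(self._items)

    def record_consensus(self, feature: str, normalized_label: str,
                         annotator_a: int, annotator_b: int,
                         adjudicator: int | None = None,
                         store: ConceptStore | None = None) -> MappingItem:
        """Reconcile two independent annotations for one item.

        Agreement yields the common choice; disagreement is settled by the
        adjudicator (or left pending when none is supplied). When a store is
        given and the item carries a registered local concept, the consensus
        is appended as a ``Maps to`` relationship.
        """
        item = self.get(feature, normalized_label)
        if item is None:
            raise InputError(f"no ledger item {(feature, normalized_label)}")
        item.annotator_a = annotator_a
        item.annotator_b = annotator_b
        if annotator_a == annotator_b:
            item.consensus = annotator_a
            item.adjudicated = False
        elif adjudicator is not None:
            item.consensus = adjudicator
            item.adjudicated = True
        else:
            item.consensus = None  # pending third-expert review
            item.adjudicated = False
        if (store is not None and item.consensus is not None
                and item.local_concept_id is not None):
            store.add_relationship(item.local_concept_id, item.consensus, "Maps to")
        return item

    def kappa(self) -> KappaResult:
        pairs = [(i.annotator_a, i.annotator_b) for i in self._items.values()
                 if i.annotator_a is not None and i.annotator_b is not None]
        return cohen_kappa([p[0] for p in pairs], [p[1] for p in pairs])

    # -- persistence --------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(i) for i in self._items.values()])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MappingLedger":
        ledger = cls()
        df = pd.read_csv(path, keep_default_na=False)
        for row in df.to_dict("records"):
            for col in ("annotator_a", "annotator_b", "consensus",
                        "local_concept_id", "source_concept_id"):
                row[col] = int(float(row[col])) if row[col] not in ("", None) else None
            row["adjudicated"] = str(row["adjudicated"]) in ("True", "true", "1")
            row["difficulty_level"] = int(row["difficulty_level"])
            row["n_records"] = int(row["n_records"])
            ledger.add(MappingItem(**row))
        return ledger


# ---------------------------------------------------------------------------
# coverage report
# ---------------------------------------------------------------------------

def percent(n: int, total: int) -> float:
    """Percentage rounded to one decimal, half away from zero."""
    if total == 0:
        return 0.0
    value = Decimal(100) * Decimal(n) / Decimal(total)
    sign = -1 if value < 0 else 1
    return sign * float(abs(value).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoverageRow:
    feature: str
    source_vocabulary: str
    target_vocabulary: str
    difficulty_level: int
    n_concepts: int
    mapped_concepts: tuple[int, int, float] | None  # (n, N, %)
    mapped_records: tuple[int, int, float] | None


def coverage_report(ledger: MappingLedger) -> list[CoverageRow]:
    """Concept- and record-level mapping coverage per (feature, vocabulary).

    Level-4 (free text) rows carry no mapping fractions — they are out of
    mapping scope by definition.
    """
    groups: dict[tuple, list[MappingItem]] = {}
    for item in ledger.items:
        groups.setdefault((item.feature, item.source_vocabulary,
                           item.target_vocabulary, item.difficulty_level), []).append(item)
    rows = []
    for (feature, src, tgt, level), items in sorted(groups.items()):
        n_concepts = len(items)
        if level == 4:
            rows.append(CoverageRow(feature, src, tgt, level, n_concepts, None, None))
            continue
        mapped = [i for i in items if i.consensus is not None]
        n_rec = sum(i.n_records for i in items)
        n_rec_mapped = sum(i.n_records for i in mapped)
        rows.append(CoverageRow(
            feature, src, tgt, level, n_concepts,
            (len(mapped), n_concepts, percent(len(mapped), n_concepts)),
            (n_rec_mapped, n_rec, percent(n_rec_mapped, n_rec))))
    return rows


def coverage_frame(rows: list[CoverageRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        rec = {"feature": r.feature, "source_vocabulary": r.source_vocabulary,
               "target_vocabulary": r.target_vocabulary,
               "difficulty_level": r.difficulty_level, "n_concepts": r.n_concepts}
        if r.mapped_concepts:
            rec.update(mapped_concepts_n=r.mapped_concepts[0],
                       mapped_concepts_total=r.mapped_concepts[1],
                       mapped_concepts_pct=r.mapped_concepts[2])
        if r.mapped_records:
            rec.update(mapped_records_n=r.mapped_records[0],
                       mapped_records_total=r.mapped_records[1],
                       mapped_records_pct=r.mapped_records[2])
        records.append(rec)
    return pd.DataFrame(records)
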