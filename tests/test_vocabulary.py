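"""Vocabulary layer: fixture integrity, normalization, difficulty levels,
two-hop drug mapping, local-concept registration, κ and coverage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caretl import (Concept, ConceptStore, MappingItem, MappingLedger, SourceItem,
                    bundled_store, classify_difficulty, cohen_kappa,
                    coverage_report, load_vocabulary_fixture, map_drug,
                    normalize_label, percent)
from caretl.errors import InputError, IntegrityError
from caretl.vocabulary import LOCAL_ID_FLOOR, suggest_candidates


# -- fixture loading ---------------------------------------------------------

def test_bundled_fixture_loads_clean():
    store = bundled_store()
    assert store.n_concepts >= 100
    assert store.n_relationships >= 30
    vocabs = {c.vocabulary_id for c in store.concepts}
    assert {"ICD10", "LOINC", "SNOMED", "ATC", "RxNorm", "UCUM", "CIP"} <= vocabs
    # every standard fixture id stays below the local-id floor
    assert all(c.concept_id <= LOCAL_ID_FLOOR for c in store.concepts)


def test_small_fixture_sizes(tmp_path):
    (tmp_path / "VOCABULARY.csv").write_text(
        "vocabulary_id,vocabulary_name\nLOINC,LOINC\n")
    (tmp_path / "CONCEPT.csv").write_text(
        "concept_id,concept_name,domain_id,vocabulary_id,concept_code,standard_concept\n"
        + "\n".join(f"{i},c{i},Measurement,LOINC,code{i},S" for i in range(1, 11)) + "\n")
    (tmp_path / "CONCEPT_RELATIONSHIP.csv").write_text(
        "concept_id_1,concept_id_2,relationship_id\n"
        + "\n".join(f"{i},{i + 1},Maps to" for i in range(1, 5)) + "\n")
    store = load_vocabulary_fixture(tmp_path)
    assert (store.n_concepts, store.n_relationships) == (10, 4)


def test_dangling_relationship_rejected(tmp_path):
    (tmp_path / "VOCABULARY.csv").write_text("vocabulary_id,vocabulary_name\nLOINC,L\n")
    (tmp_path / "CONCEPT.csv").write_text(
        "concept_id,concept_name,domain_id,vocabulary_id,concept_code,standard_concept\n"
        "1,c1,Measurement,LOINC,x,S\n")
    (tmp_path / "CONCEPT_RELATIONSHIP.csv").write_text(
        "concept_id_1,concept_id_2,relationship_id\n1,999,Maps to\n")
    with pytest.raises(IntegrityError, match="999"):
        load_vocabulary_fixture(tmp_path)


def test_duplicate_concept_id_rejected():
    store = ConceptStore()
    store.add_concept(Concept(1, "a", "LOINC", "x", True, "Measurement"))
    with pytest.raises(IntegrityError, match="duplicate"):
        store.add_concept(Concept(1, "b", "LOINC", "y", True, "Measurement"))


def test_maps_to_requires_standard_target():
    store = ConceptStore()
    store.add_concept(Concept(1, "a", "ATC", "x", False, "Drug"))
    store.add_concept(Concept(2, "b", "ATC", "y", False, "Drug"))
    with pytest.raises(IntegrityError, match="standard"):
        store.add_relationship(1, 2, "Maps to")


# -- normalization -----------------------------------------------------------

def test_normalize_crp_abbreviation_expansion():
    assert normalize_label("CRP", {"CRP": "C-reactive protein"}, set()) \
        == "c-reactive protein"
    # the bundled abbreviation dictionary carries the same expansion
    assert normalize_label("CRP") == "c-reactive protein"


def test_normalize_whitespace_collapse():
    assert normalize_label("  creatinine ") == "creatinine"


def test_normalize_rule_sequence():
    # strip leading line number, drop punctuation, case-fold, keep stopword-free tokens
    assert normalize_label("3. Potassium (mmol/L):", {}, {"of", "to", "an"}) \
        == "potassium mmol l"


def test_normalize_stopwords_and_accents():
    assert normalize_label("Glycémie à jeun", {}, {"a"}) == "glycemie jeun"


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(max_size=40))
def test_normalize_idempotent(raw):
    once = normalize_label(raw, {"CRP": "C-reactive protein"}, {"of", "to", "an"})
    twice = normalize_label(once, {"CRP": "C-reactive protein"}, {"of", "to", "an"})
    assert once == twice


def test_fuzzy_suggestions_propose_only():
    store = bundled_store()
    hits = suggest_candidates("Body weigth", store, domain="Measurement",
                              threshold=0.85)
    assert hits and hits[0][0].name == "Body weight"
    assert all(sim >= 0.85 for _c, sim in hits)


# -- difficulty levels -------------------------------------------------------

def test_classify_levels():
    store = bundled_store()
    # ICD-10 code that is itself standard → level 1
    assert classify_difficulty(SourceItem("E11", "ICD10", code="E11"), store) == 1
    # ATC code with a pre-existing ATC→RxNorm link → level 2
    assert classify_difficulty(SourceItem("A10BA02", "ATC", code="A10BA02"), store) == 2
    # CIP stays level 3: its CIP→ATC links are the manual-mapping artifact
    cip = store.concepts[0]
    cip_code = next(c.concept_code for c in store.concepts if c.vocabulary_id == "CIP")
    assert classify_difficulty(SourceItem(cip_code, "CIP", code=cip_code), store) == 3
    # structured but unknown → level 3
    assert classify_difficulty(SourceItem("mystery", "local"), store) == 3
    # free text → level 4
    assert classify_difficulty(
        SourceItem("douleur abdominale", "local", is_free_text=True), store) == 4


# -- drug mapping ------------------------------------------------------------

def test_map_drug_full_chain():
    store = bundled_store()
    result = map_drug("3400930000000", store)
    assert result.mapped
    assert store.get(result.atc_concept_id).vocabulary_id == "ATC"
    rx = store.get(result.rxnorm_concept_id)
    assert rx.vocabulary_id == "RxNorm" and rx.is_standard


def test_map_drug_missing_second_hop():
    store = ConceptStore()
    store.add_concept(Concept(1, "cip", "CIP", "3400900000000", False, "Drug"))
    store.add_concept(Concept(2, "atc", "ATC", "X00XX00", False, "Drug"))
    store.add_relationship(1, 2, "CIP to ATC")
    result = map_drug("3400900000000", store)
    assert not result.mapped and "second hop" in result.reason
    assert result.atc_concept_id == 2


def test_map_drug_malformed_code():
    with pytest.raises(InputError, match="13 digits"):
        map_drug("12AB", bundled_store())


def test_map_drug_partial_catalog_coverage():
    """Exhaustive traversal over a 20-code catalog with 17 full chains."""
    store = ConceptStore()
    rx = Concept(500, "ing", "RxNorm", "1", True, "Drug")
    store.add_concept(rx)
    for i in range(20):
        store.add_concept(Concept(i + 1, f"cip{i}", "CIP", f"{3400900000000 + i}",
                                  False, "Drug"))
        store.add_concept(Concept(100 + i, f"atc{i}", "ATC", f"A{i:02d}", False, "Drug"))
        store.add_relationship(i + 1, 100 + i, "CIP to ATC")
        if i < 17:
            store.add_relationship(100 + i, 500, "ATC to RxNorm")
    mapped = sum(map_drug(f"{3400900000000 + i}", store).mapped for i in range(20))
    assert mapped == 17


# -- local concept registration ---------------------------------------------

def test_register_local_sequence_and_idempotence():
    store = ConceptStore()
    first = store.register_local_concept("poids", "local", "Measurement")
    assert first.concept_id == LOCAL_ID_FLOOR + 1
    again = store.register_local_concept("poids", "local", "Measurement")
    assert again.concept_id == first.concept_id
    ids = {store.register_local_concept(f"label {i}", "local", "Measurement").concept_id
           for i in range(50)}
    assert len(ids) == 50 and all(i > LOCAL_ID_FLOOR for i in ids)


# -- consensus reconciliation ------------------------------------------------

def _ledger_with(n):
    ledger = MappingLedger()
    for i in range(n):
        ledger.add(MappingItem("laboratory", f"l{i}", f"l{i}", "local", "LOINC", 3))
    return ledger


def test_record_consensus_agreement_and_adjudication():
    ledger = _ledger_with(3)
    item = ledger.record_consensus("laboratory", "l0", 11, 11)
    assert item.consensus == 11 and not item.adjudicated
    item = ledger.record_consensus("laboratory", "l1", 11, 12, adjudicator=12)
    assert item.consensus == 12 and item.adjudicated
    item = ledger.record_consensus("laboratory", "l2", 11, 12)  # pending
    assert item.consensus is None and not item.adjudicated


def test_reconciliation_of_152_items_with_37_disagreements():
    rng = np.random.default_rng(0)
    ledger = _ledger_with(152)
    disagree = set(rng.choice(152, size=37, replace=False))
    for i in range(152):
        if i in disagree:
            ledger.record_consensus("laboratory", f"l{i}", 1, 2, adjudicator=2)
        else:
            ledger.record_consensus("laboratory", f"l{i}", 1, 1)
    assert sum(item.adjudicated for item in ledger.items) == 37
    kappa = ledger.kappa()
    assert kappa.n_disagreements == 37
    assert kappa.p_o == pytest.approx(115 / 152)


def test_consensus_appends_maps_to():
    store = ConceptStore()
    store.add_concept(Concept(10, "std", "LOINC", "x", True, "Measurement"))
    ledger = _ledger_with(1)
    item = ledger.get("laboratory", "l0")
    item.local_concept_id = store.register_local_concept(
        "l0", "local", "Measurement").concept_id
    ledger.record_consensus("laboratory", "l0", 10, 10, store=store)
    assert store.related(item.local_concept_id, "Maps to") == [10]


# -- Cohen's kappa -----------------------------------------------------------

def test_kappa_perfect_agreement():
    result = cohen_kappa(["x", "y", "x", "z"], ["x", "y", "x", "z"])
    assert result.kappa == 1.0 and result.p_o == 1.0


def test_kappa_symmetric_total_disagreement():
    result = cohen_kappa(["x", "x", "y", "y"], ["y", "y", "x", "x"])
    assert result.p_o == 0.0
    assert result.kappa == pytest.approx(-1.0)


def test_kappa_length_mismatch():
    with pytest.raises(InputError, match="mismatch"):
        cohen_kappa(["x"], ["x", "y"])


def test_kappa_single_category_degenerate():
    assert cohen_kappa(["x", "x"], ["x", "x"]).kappa == 1.0


# -- coverage report ---------------------------------------------------------

def test_percent_half_away_from_zero():
    assert percent(1, 8) == 12.5
    assert percent(1, 16) == 6.3     # 6.25 rounds away from zero
    assert percent(0, 17) == 0.0
    assert percent(17, 17) == 100.0


def test_coverage_levels_and_monotonicity():
    ledger = _ledger_with(4)
    ledger.add(MappingItem("free_text", "reason", "reason", "local", "", 4,
                           n_records=10))
    for item in ledger.items:
        item.n_records = item.n_records or 5
    ledger.record_consensus("laboratory", "l0", 1, 1)
    before = {(r.feature, r.difficulty_level): r for r in coverage_report(ledger)}
    assert before[("free_text", 4)].mapped_concepts is None
    assert before[("laboratory", 3)].mapped_concepts == (1, 4, 25.0)
    # mapping one more item never decreases any percentage
    ledger.record_consensus("laboratory", "l1", 1, 1)
    after = {(r.feature, r.difficulty_level): r for r in coverage_report(ledger)}
    assert after[("laboratory", 3)].mapped_concepts[2] >= 25.0
    assert after[("laboratory", 3)].mapped_records[2] >= \
        before[("laboratory", 3)].mapped_records[2]
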