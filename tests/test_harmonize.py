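"""Field map, term mappings and MVLD -> CIViC precuration generation."""

import pytest

from mvldkit import (
    CANONICAL_COLUMNS,
    field_map,
    map_consequence,
    map_effect_term,
    mapping_report,
    mvld_to_precuration,
    precuration_field_audit,
    validate_evidence_item,
    VocabularyError,
)
from mvldkit.harmonize import (
    SOMATIC_PROVENANCE_NOTES,
    map_prognostic_effect,
    parse_cancer_type,
)
from mvldkit.vocab import EFFECT_TERMS, SIGNIFICANCE_BY_TYPE


# ---------------------------------------------------------------- field map

def test_field_map_covers_all_18_fields_exactly_once():
    entries = field_map()
    assert len(entries) == 18
    assert sorted(e.mvld_field for e in entries) == sorted(CANONICAL_COLUMNS)


def test_all_six_allele_descriptive_fields_map_directly():
    direct_ad = [
        e for e in field_map()
        if e.mvld_category == "Allele Descriptive" and e.mapping_class == "direct"
    ]
    assert len(direct_ad) == 6


def test_mapping_class_invariants_hold_per_entry():
    for e in field_map():
        if e.mapping_class == "direct":
            assert e.civic_target and e.workaround_note is None, e.mvld_field
        elif e.mapping_class == "relatable":
            assert e.civic_target and e.workaround_note, e.mvld_field
        else:
            assert e.mapping_class == "nonmappable" and e.civic_target is None, e.mvld_field


def test_known_entry_classifications():
    by_field = {e.mvld_field: e for e in field_map()}
    somatic = by_field["somatic_classification"]
    assert somatic.mapping_class == "relatable"
    assert "control sequencing" in somatic.workaround_note.lower()
    sub_level = by_field["sub_level_of_evidence"]
    assert sub_level.mapping_class == "nonmappable"
    assert sub_level.civic_target is None
    assert by_field["variant_type"].mapping_class == "relatable"


# ------------------------------------------------------------- term mapping

@pytest.mark.parametrize(
    "effect, expected",
    [
        ("Sensitive", "Sensitivity/Response"),
        ("Responsive", "Sensitivity/Response"),
        ("Resistant", "Resistance"),
        ("Not-Responsive", "Resistance"),
        ("Reduced Sensitivity", "Reduced Sensitivity"),
    ],
)
def test_effect_term_mapping(effect, expected):
    assert map_effect_term(effect) == expected


def test_effect_mapping_is_total_onto_predictive_vocabulary():
    assert len(EFFECT_TERMS) == 5
    for term in EFFECT_TERMS:
        assert map_effect_term(term) in SIGNIFICANCE_BY_TYPE["Predictive"]
        assert map_prognostic_effect(term) in SIGNIFICANCE_BY_TYPE["Prognostic"]


def test_unknown_effect_term_is_a_vocabulary_error():
    with pytest.raises(VocabularyError):
        map_effect_term("Hypersensitive")


@pytest.mark.parametrize(
    "term, expected",
    [
        ("missense_variant", "missense_variant"),
        ("Missense Variant", "missense_variant"),
        ("  STOP_GAINED ", "stop_gained"),
    ],
)
def test_consequence_mapping_normalizes_to_so(term, expected):
    assert map_consequence(term) == expected


def test_unknown_consequence_is_rejected():
    with pytest.raises(VocabularyError):
        map_consequence("banana_variant")


def test_cancer_type_parsing_branches():
    d = parse_cancer_type("Melanoma [DOID:1909]")
    assert (d.name, d.doid) == ("Melanoma", "1909")
    d = parse_cancer_type("Rare Sarcoma NOS")
    assert (d.name, d.doid) == ("Rare Sarcoma NOS", None)


# ------------------------------------------------------------- precuration

def test_one_evidence_stub_per_pmid(worked):
    record, _ = worked
    precur = mvld_to_precuration(record)
    assert len(precur.evidence_stubs) == len(record.allele_interpretive.pmids) == 3
    assert [s.pmid for s in precur.evidence_stubs] == record.allele_interpretive.pmids


def test_unknown_origin_note_in_every_stub(worked):
    record, _ = worked
    rec = record.model_copy(deep=True)
    rec.allele_interpretive.somatic_classification = "Unknown"
    precur = mvld_to_precuration(rec)
    note = SOMATIC_PROVENANCE_NOTES["Unknown"]
    assert precur.evidence_stubs
    assert all(note in s.statement for s in precur.evidence_stubs)


def test_predictive_resistant_record_maps_to_resistance_with_drugs(worked):
    record, _ = worked
    rec = record.model_copy(deep=True)
    rec.somatic_interpretive.effect = "Resistant"
    precur = mvld_to_precuration(rec)
    for stub in precur.evidence_stubs:
        assert stub.clinical_significance == "Resistance"
        assert stub.drugs == ["Dabrafenib"]
        assert stub.evidence_type == "Predictive"


def test_invalid_record_is_rejected_citing_the_report(worked):
    record, _ = worked
    rec = record.model_copy(deep=True)
    rec.somatic_interpretive.therapeutic_context = ""
    with pytest.raises(ValueError, match="MVLD-R3"):
        mvld_to_precuration(rec)


def test_stubs_pass_evidence_validation(clean_set):
    for record in clean_set.mvld_records[:15]:
        precur = mvld_to_precuration(record)
        for stub in precur.evidence_stubs:
            report = validate_evidence_item(stub)
            assert report.is_valid, [str(i) for i in report.issues]
            # the only open items are curator content (rating), as warnings
            assert {i.rule_id for i in report.warnings} <= {"EV-W1"}


def test_no_information_is_lost_in_precuration(clean_set):
    """Every MVLD field value is recoverable from the precuration output
    (mapped field, statement note, or unmapped bucket)."""
    for record in clean_set.mvld_records:
        audit = precuration_field_audit(record, mvld_to_precuration(record))
        lost = [f for f, ok in audit.items() if not ok]
        assert lost == []


def test_nonmappable_values_survive_verbatim(worked):
    record, _ = worked
    precur = mvld_to_precuration(record)
    assert precur.unmapped["sub_level_of_evidence"] == (
        record.somatic_interpretive.sub_level_of_evidence
    )
    assert precur.unmapped["variant_type"] == record.allele_interpretive.variant_type


# ----------------------------------------------------------- mapping report

def test_mapping_report_empty_input():
    report = mapping_report([])
    assert report["n_records"] == 0
    assert all(v["count"] == 0 for v in report["field_population"].values())
    assert report["class_value_counts"] == {"direct": 0, "relatable": 0, "nonmappable": 0}


def test_mapping_report_fully_populated_batch(worked):
    record, _ = worked
    report = mapping_report([record] * 10)
    assert report["n_records"] == 10
    assert all(v["rate"] == 1.0 for v in report["field_population"].values())


def test_mapping_report_matches_independent_tally(clean_set):
    records = clean_set.mvld_records
    report = mapping_report(records)
    class_of = {e.mvld_field: e.mapping_class for e in field_map()}
    # brute-force per-record tally, independent of the report loop
    for field in CANONICAL_COLUMNS:
        expected = sum(1 for r in records if r.to_columns()[field] != "")
        assert report["field_population"][field]["count"] == expected
    for cls in ("direct", "relatable", "nonmappable"):
        expected = sum(
            1
            for r in records
            for field in CANONICAL_COLUMNS
            if class_of[field] == cls and r.to_columns()[field] != ""
        )
        assert report["class_value_counts"][cls] == expected
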