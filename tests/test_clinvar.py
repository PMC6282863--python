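"""ClinVar field classification, condition-ID logic and submission sheets."""

import pytest

from mvldkit import (
    assertion_to_row,
    classify_clinvar_fields,
    ClinVarExportError,
    ClinVarSubmissionRow,
    derive_condition_id,
    Disease,
    read_submission,
    SUBMISSION_COLUMNS,
    validate_submission_row,
    write_submission,
)
from mvldkit.clinvar import AMP_CRITERIA_CITATION


# ------------------------------------------------------ field classification

def test_layout_partitions_into_exactly_three_classes():
    specs = classify_clinvar_fields()
    classes = {s.field_class for s in specs}
    assert classes == {"variant_direct", "assertion_mapped", "procedural"}
    counts = {c: sum(1 for s in specs if s.field_class == c) for c in classes}
    assert sum(counts.values()) == len(specs) == len(SUBMISSION_COLUMNS) == 22
    # every column appears exactly once
    assert len({s.column_name for s in specs}) == len(specs)


def test_exactly_two_columns_need_condition_logic():
    flagged = [s for s in classify_clinvar_fields() if s.needs_logic]
    assert {s.column_name for s in flagged} == {"Condition ID type", "Condition ID value"}
    assert all(s.field_class == "assertion_mapped" for s in flagged)


@pytest.mark.parametrize(
    "column, field_class",
    [
        ("Chromosome", "variant_direct"),
        ("Start", "variant_direct"),
        ("HGVS", "variant_direct"),
        ("Clinical significance", "assertion_mapped"),
        ("Citations", "assertion_mapped"),
        ("Collection method", "procedural"),
        ("Local ID", "procedural"),
        ("Allele origin", "procedural"),
    ],
)
def test_known_column_classifications(column, field_class):
    spec = next(s for s in classify_clinvar_fields() if s.column_name == column)
    assert spec.field_class == field_class


# ----------------------------------------------------------- condition IDs

def test_condition_id_with_doid():
    assert derive_condition_id(Disease(name="Chronic Myeloid Leukemia", doid="8552")) == (
        "DOID", "8552", "Chronic Myeloid Leukemia"
    )


def test_condition_id_without_doid_uses_preferred_name_only():
    assert derive_condition_id(Disease(name="Rare Sarcoma NOS", doid=None)) == (
        "", "", "Rare Sarcoma NOS"
    )


def test_empty_disease_name_is_an_export_error():
    with pytest.raises(ClinVarExportError):
        derive_condition_id(Disease(name="", doid=None))


# ------------------------------------------------------------- row building

def test_worked_example_row_fields(worked):
    _, bundle = worked
    row = assertion_to_row(bundle.assertions[0], bundle.variants[0], bundle.evidence_items)
    assert row.local_id == "CIViC:AID5"
    assert row.allele_origin == "somatic"
    assert row.affected_status == "yes"
    assert row.collection_method == "curation"
    assert row.assertion_criteria_citation == AMP_CRITERIA_CITATION
    assert row.clinical_significance == "drug response"
    assert row.drug_response_condition == "Dabrafenib"
    assert row.condition_id_type == "DOID" and row.condition_id_value == "1909"
    assert row.hgvs == "NC_000007.13:g.140453136A>T"
    assert row.attribution == "ClinGen Somatic WG"


def test_citations_are_deduplicated_and_ascending(worked):
    _, bundle = worked
    b = bundle.model_copy(deep=True)
    b.evidence_items[0].pmid = "222"
    b.evidence_items[1].pmid = "111"
    b.evidence_items[2].pmid = "222"
    row = assertion_to_row(b.assertions[0], b.variants[0], b.evidence_items)
    assert row.citations == "111|222"


def test_prognostic_assertion_renders_via_rule_table(worked):
    _, bundle = worked
    b = bundle.model_copy(deep=True)
    a = b.assertions[0]
    a.assertion_type = "Prognostic"
    a.drugs = []
    a.clinical_significance = "Poor Outcome"
    for e in b.evidence_items:  # keep them resolvable but neutral
        e.evidence_type = "Prognostic"
        e.clinical_significance = "Poor Outcome"
        e.drugs = []
    row = assertion_to_row(a, b.variants[0], b.evidence_items)
    assert row.clinical_significance == "other"
    assert row.drug_response_condition == ""


def test_invalid_assertion_is_rejected_with_report(worked):
    _, bundle = worked
    b = bundle.model_copy(deep=True)
    b.assertions[0].amp.level = "Level C"
    with pytest.raises(ClinVarExportError, match="AS-R1"):
        assertion_to_row(b.assertions[0], b.variants[0], b.evidence_items)


def test_exported_rows_pass_the_internal_schema_check(clean_set):
    bundle = clean_set.bundle
    for a in bundle.assertions:
        v = bundle.variant_by_id(a.variant_id)
        row = assertion_to_row(a, v, bundle.evidence_items)
        report = validate_submission_row(row)
        assert report.is_valid, [str(i) for i in report.issues]


def test_schema_check_catches_bad_rows(worked):
    _, bundle = worked
    row = assertion_to_row(bundle.assertions[0], bundle.variants[0], bundle.evidence_items)
    bad = row.model_copy(update={"local_id": "AID5", "reference_allele": "N",
                                 "allele_origin": "germline"})
    rules = {i.rule_id for i in validate_submission_row(bad).errors}
    assert {"CV-R1", "CV-R2", "CV-R5"} <= rules


# -------------------------------------------------------------- sheet I/O

def _rows(clean_set):
    bundle = clean_set.bundle
    return [
        assertion_to_row(a, bundle.variant_by_id(a.variant_id), bundle.evidence_items)
        for a in bundle.assertions
    ]


def test_sheet_round_trip_and_determinism(clean_set, tmp_path):
    rows = _rows(clean_set)
    first, second, third = (tmp_path / n for n in ("a.tsv", "b.tsv", "c.tsv"))
    write_submission(rows, first)
    back = read_submission(first)
    assert back == rows
    write_submission(back, second)
    write_submission(rows, third)
    assert first.read_bytes() == second.read_bytes() == third.read_bytes()
    assert len(first.read_text().splitlines()) == len(rows) + 1


def test_empty_sheet_is_header_only(tmp_path):
    path = tmp_path / "empty.tsv"
    write_submission([], path)
    assert path.read_text().splitlines() == ["\t".join(SUBMISSION_COLUMNS)]
    assert read_submission(path) == []


def test_renamed_column_is_a_dialect_error(clean_set, tmp_path):
    rows = _rows(clean_set)[:1]
    path = tmp_path / "renamed.tsv"
    write_submission(rows, path)
    text = path.read_text().replace("Gene symbol", "Gene Symbol", 1)
    path.write_text(text, encoding="utf-8")
    with pytest.raises(ClinVarExportError, match="Gene symbol"):
        read_submission(path)


def test_hand_built_row_parses_to_its_constructor(tmp_path):
    row = ClinVarSubmissionRow(
        local_id="CIViC:AID1",
        gene_symbol="EGFR",
        chromosome="7",
        start=55259515,
        stop=55259515,
        reference_allele="T",
        alternate_allele="G",
        assembly="GRCh37",
        hgvs="NC_000007.13:g.55259515T>G",
        preferred_condition_name="Lung Non-small Cell Carcinoma",
        clinical_significance="drug response",
        drug_response_condition="Erlotinib",
        citations="15118073",
        comment="EGFR L858R confers sensitivity to EGFR TKIs.",
    )
    path = tmp_path / "hand.tsv"
    path.write_text(
        "\t".join(SUBMISSION_COLUMNS) + "\n" + "\t".join(row.to_cells()) + "\n",
        encoding="utf-8",
    )
    assert read_submission(path) == [row]
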