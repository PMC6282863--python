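"""CIViC assertion → ClinVar submission-sheet transformation.

Every column of the frozen 22-column submission layout is classified into
one of exactly three generation classes:

* ``variant_direct`` — copied from CIViC variant fields with no
  alteration (coordinates, alleles, assembly, genomic HGVS);
* ``assertion_mapped`` — drawn from CIViC assertion fields, with two
  columns (Condition ID type / Condition ID value) requiring extra logic
  to format the disease-ontology identifier;
* ``procedural`` — generated by rule (constants such as allele origin
  "somatic", the local-ID convention ``CIViC:AID<n>``, the AMP guideline
  citation).

The sheet is a pinned UTF-8 TSV dialect (ClinVar's real template is a
versioned workbook; this package freezes one text dialect and documents
it rather than tracking template drift). Export is deterministic: the
same inputs always produce byte-identical files.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

from pydantic import BaseModel

from .civic import (
    Assertion,
    CivicVariant,
    Disease,
    EvidenceItem,
    build_genomic_hgvs,
    validate_assertion,
)
from .validation import ValidationReport
from .vocab import GENOME_BUILDS

__all__ = [
    "ClinVarFieldSpec",
    "ClinVarSubmissionRow",
    "ClinVarExportError",
    "SUBMISSION_COLUMNS",
    "AMP_CRITERIA_CITATION",
    "AMP_CRITERIA_METHOD",
    "classify_clinvar_fields",
    "derive_condition_id",
    "assertion_to_row",
    "validate_submission_row",
    "write_submission",
    "read_submission",
]

#: Citation for the AMP/ASCO/CAP somatic interpretation guidelines used as
#: the assertion criteria on every exported row (frozen constant).
AMP_CRITERIA_CITATION = "PMID:27993330"
AMP_CRITERIA_METHOD = "AMP-ASCO-CAP somatic variant interpretation guidelines"


class ClinVarExportError(ValueError):
    """An assertion bundle cannot be rendered as a submission row."""


class ClinVarFieldSpec(BaseModel):
    """Classification of one submission-sheet column."""

    column_name: str
    field_class: str  # "variant_direct" | "assertion_mapped" | "procedural"
    source: str
    needs_logic: bool = False


@lru_cache(maxsize=1)
def _layout() -> tuple[ClinVarFieldSpec, ...]:
    text = resources.files("mvldkit.data").joinpath("clinvar_layout.tsv").read_text("utf-8")
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    return tuple(
        ClinVarFieldSpec(
            column_name=row["column_name"],
            field_class=row["field_class"],
            source=row["source"],
            needs_logic=row["needs_logic"] == "1",
        )
        for row in reader
    )


def classify_clinvar_fields() -> list[ClinVarFieldSpec]:
    """The frozen column classification: a disjoint three-class partition
    of the full submission layout, with exactly the Condition ID type and
    Condition ID value columns flagged as needing additional logic."""
    return list(_layout())


#: Frozen submission-sheet column order.
SUBMISSION_COLUMNS: tuple[str, ...] = tuple(s.column_name for s in _layout())

# column label -> row attribute, in layout order
_COLUMN_ATTRS: dict[str, str] = {
    "Local ID": "local_id",
    "Gene symbol": "gene_symbol",
    "Chromosome": "chromosome",
    "Start": "start",
    "Stop": "stop",
    "Reference allele": "reference_allele",
    "Alternate allele": "alternate_allele",
    "Assembly": "assembly",
    "HGVS": "hgvs",
    "Condition ID type": "condition_id_type",
    "Condition ID value": "condition_id_value",
    "Preferred condition name": "preferred_condition_name",
    "Clinical significance": "clinical_significance",
    "Drug response condition": "drug_response_condition",
    "Allele origin": "allele_origin",
    "Affected status": "affected_status",
    "Collection method": "collection_method",
    "Assertion criteria citation": "assertion_criteria_citation",
    "Assertion criteria method": "assertion_criteria_method",
    "Citations": "citations",
    "Comment": "comment",
    "Attribution": "attribution",
}


class ClinVarSubmissionRow(BaseModel):
    """One flat row of the pinned ClinVar submission-sheet dialect."""

    local_id: str
    gene_symbol: str
    chromosome: str
    start: int
    stop: int
    reference_allele: str
    alternate_allele: str
    assembly: str
    hgvs: str
    condition_id_type: str = ""
    condition_id_value: str = ""
    preferred_condition_name: str = ""
    clinical_significance: str = ""
    drug_response_condition: str = ""
    allele_origin: str = "somatic"
    affected_status: str = "yes"
    collection_method: str = "curation"
    assertion_criteria_citation: str = AMP_CRITERIA_CITATION
    assertion_criteria_method: str = AMP_CRITERIA_METHOD
    citations: str = ""
    comment: str = ""
    attribution: str = ""

    def to_cells(self) -> list[str]:
        return [str(getattr(self, _COLUMN_ATTRS[c])) for c in SUBMISSION_COLUMNS]

    @classmethod
    def from_cells(cls, cells: list[str]) -> "ClinVarSubmissionRow":
        kwargs = dict(zip((_COLUMN_ATTRS[c] for c in SUBMISSION_COLUMNS), cells))
        kwargs["start"] = int(kwargs["start"])
        kwargs["stop"] = int(kwargs["stop"])
        return cls(**kwargs)


@lru_cache(maxsize=1)
def _significance_table() -> dict[tuple[str, str], str]:
    text = resources.files("mvldkit.data").joinpath(
        "clinvar_significance_map.tsv"
    ).read_text("utf-8")
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    return {
        (row["assertion_type"], row["civic_significance"]): row["clinvar_significance"]
        for row in reader
    }


def derive_condition_id(disease: Disease) -> tuple[str, str, str]:
    """(condition_id_type, condition_id_value, preferred_condition_name).

    CIViC diseases carry Disease Ontology identifiers: when a DOID is
    present the ID type is ``"DOID"`` with the bare numeric value and the
    preferred name is still emitted; without one, both ID fields stay
    empty and the preferred name alone identifies the condition.
    """
    if not disease.name.strip():
        raise ClinVarExportError("disease name is empty; cannot derive a condition")
    if disease.doid:
        value = disease.doid.strip()
        if not value.isdigit():
            raise ClinVarExportError(f"DOID {disease.doid!r} is not a bare numeric identifier")
        return "DOID", value, disease.name
    return "", "", disease.name


def _render_significance(a: Assertion) -> tuple[str, str]:
    """(clinical_significance, drug_response_condition) for an assertion."""
    if a.assertion_type == "Predictive":
        return "drug response", "|".join(a.drugs)
    civic_term = a.clinical_significance or "N/A"
    key = (a.assertion_type, civic_term)
    table = _significance_table()
    if key not in table:
        raise ClinVarExportError(
            f"no ClinVar significance rule for {a.assertion_type} assertions with "
            f"CIViC significance {civic_term!r}"
        )
    return table[key], ""


def assertion_to_row(
    a: Assertion,
    v: CivicVariant,
    evidence: list[EvidenceItem],
    organization: Optional[str] = None,
) -> ClinVarSubmissionRow:
    """Render one validated assertion as a submission row.

    Fills every column per its :class:`ClinVarFieldSpec`: variant fields
    copy over unaltered (the genomic HGVS is built from them), assertion
    fields map through the condition-ID and significance rules, and the
    procedural columns are generated (``CIViC:AID<n>`` local ID, somatic
    allele origin, curation collection method, AMP criteria citation).
    Citations are the deduplicated, ascending PMIDs of the supporting
    evidence items. Assertions that fail validation are rejected with the
    report's findings.
    """
    report = validate_assertion(a, evidence)
    if not report.is_valid:
        msgs = "; ".join(str(e) for e in report.errors)
        raise ClinVarExportError(f"assertion AID{a.aid} fails validation: {msgs}")
    if not v.chromosome or v.start < 1 or v.stop < 1 or not v.reference_build:
        raise ClinVarExportError(f"variant {v.variant_id} has incomplete coordinates")

    cond_type, cond_value, preferred = derive_condition_id(a.disease)
    significance, drug_condition = _render_significance(a)
    by_eid = {e.eid: e for e in evidence}
    pmids = sorted(
        {by_eid[eid].pmid for eid in a.evidence_ids if by_eid[eid].pmid}, key=int
    )
    return ClinVarSubmissionRow(
        local_id=f"CIViC:AID{a.aid}",
        gene_symbol=v.gene_symbol,
        chromosome=v.chromosome,
        start=v.start,
        stop=v.stop,
        reference_allele=v.reference_bases,
        alternate_allele=v.variant_bases,
        assembly=v.reference_build,
        hgvs=build_genomic_hgvs(v),
        condition_id_type=cond_type,
        condition_id_value=cond_value,
        preferred_condition_name=preferred,
        clinical_significance=significance,
        drug_response_condition=drug_condition,
        citations="|".join(pmids),
        comment=a.summary,
        attribution=organization if organization is not None else (a.organization or ""),
    )


def validate_submission_row(row: ClinVarSubmissionRow) -> ValidationReport:
    """Internal schema check applied to exported rows.

    * ``CV-R1`` — local ID matches ``CIViC:AID<n>``
    * ``CV-R2`` — alleles over ACGT, not both empty
    * ``CV-R3`` — start <= stop, positive
    * ``CV-R4`` — assembly in the allowed build set
    * ``CV-R5`` — procedural constants hold (somatic origin, curation)
    * ``CV-R6`` — citations are ``|``-joined integers, ascending, unique
    """
    rep = ValidationReport()
    import re

    if not re.match(r"^CIViC:AID\d+$", row.local_id):
        rep.error("CV-R1", "local_id", f"{row.local_id!r} does not match CIViC:AID<n>")
    for which, allele in (("reference", row.reference_allele),
                          ("alternate", row.alternate_allele)):
        if not re.match(r"^[ACGT]*$", allele):
            rep.error("CV-R2", f"{which}_allele", f"{allele!r} contains non-ACGT characters")
    if not row.reference_allele and not row.alternate_allele:
        rep.error("CV-R2", "reference_allele", "reference and alternate alleles both empty")
    if row.start < 1 or row.start > row.stop:
        rep.error("CV-R3", "start", f"invalid coordinate span {row.start}..{row.stop}")
    if row.assembly not in GENOME_BUILDS:
        rep.error("CV-R4", "assembly", f"{row.assembly!r} not in {GENOME_BUILDS}")
    if row.allele_origin != "somatic":
        rep.error("CV-R5", "allele_origin", "allele origin must be 'somatic'")
    if row.collection_method != "curation":
        rep.error("CV-R5", "collection_method", "collection method must be 'curation'")
    if row.citations:
        parts = row.citations.split("|")
        if not all(p.isdigit() for p in parts):
            rep.error("CV-R6", "citations", "citations must be |-joined PMIDs")
        elif [int(p) for p in parts] != sorted({int(p) for p in parts}):
            rep.error("CV-R6", "citations", "citations must be unique and ascending")
    return rep


def write_submission(rows: list[ClinVarSubmissionRow], path: str | Path) -> None:
    """Write a submission sheet: UTF-8 TSV, frozen column order, one
    header row. Deterministic, and round-trips through
    :func:`read_submission` cell-for-cell."""
    lines = ["\t".join(SUBMISSION_COLUMNS)]
    for row in rows:
        lines.append("\t".join(row.to_cells()))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_submission(path: str | Path) -> list[ClinVarSubmissionRow]:
    """Read a sheet written by :func:`write_submission`; the header must
    match the frozen layout exactly (missing/extra columns are listed)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ClinVarExportError("empty file: submission sheet requires a header row")
    header = lines[0].split("\t")
    if header != list(SUBMISSION_COLUMNS):
        missing = [c for c in SUBMISSION_COLUMNS if c not in header]
        extra = [c for c in header if c not in SUBMISSION_COLUMNS]
        raise ClinVarExportError(
            "submission header does not match the frozen layout; "
            f"missing: {missing or 'none'}; unexpected: {extra or 'none'}"
        )
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ClinVarExportError(
                f"row {lineno}: expected {len(header)} cells, found {len(cells)}"
            )
        rows.append(ClinVarSubmissionRow.from_cells(cells))
    return rows
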