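"""MVLD → CIViC harmonization.

Implements the frozen field-by-field mapping table (every one of the 18
canonical MVLD fields classified as *direct*, *relatable* or
*nonmappable*), the five-term effect → clinical-significance mapping, the
Sequence Ontology consequence pass-through, and the generation of CIViC
precuration stubs from validated MVLD records — one draft evidence item
per PMID, with the somatic-classification provenance rendered as a fixed
sentence in each Evidence Statement.

The mapping tables ship as TSV data files inside the package; callers may
supply amended tables via the ``table_path`` arguments to revise terms
without code changes.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field

from .civic import (
    AmpClassification,
    CivicVariant,
    Disease,
    EvidenceItem,
)
from .alleles import derived_coordinates
from .mvld import CANONICAL_COLUMNS, MVLDRecord, validate_mvld_record
from .vocab import EFFECT_TERMS, normalize_so_term, nearest_so_term, so_terms

__all__ = [
    "FieldMapEntry",
    "CivicPrecuration",
    "VocabularyError",
    "field_map",
    "map_effect_term",
    "map_prognostic_effect",
    "map_consequence",
    "mvld_to_precuration",
    "mapping_report",
    "precuration_field_audit",
    "parse_cancer_type",
    "SOMATIC_PROVENANCE_NOTES",
]


class VocabularyError(ValueError):
    """A term falls outside the controlled vocabulary it must belong to."""


class FieldMapEntry(BaseModel):
    """One row of the MVLD → CIViC mapping table."""

    mvld_category: str
    mvld_field: str
    mapping_class: str  # "direct" | "relatable" | "nonmappable"
    civic_target: Optional[str] = None
    workaround_note: Optional[str] = None


class CivicPrecuration(BaseModel):
    """A CIViC-shaped draft generated from one MVLD record.

    ``variant`` has no identifiers and an unresolved registry ID;
    ``evidence_stubs`` holds one draft evidence item per source PMID;
    ``amp`` carries the record's AMP level-of-evidence, to be applied on
    the assertion eventually built from the stubs; ``unmapped`` retains
    verbatim every MVLD field value with no CIViC home (expert-opinion
    sub-level of evidence, the free-text variant category) so nothing is
    silently dropped.
    """

    variant: CivicVariant
    evidence_stubs: list[EvidenceItem] = Field(default_factory=list)
    amp: Optional[AmpClassification] = None
    unmapped: dict[str, str] = Field(default_factory=dict)


# Fixed provenance sentences appended to every stub Evidence Statement;
# frozen so downstream checks can assert containment.
SOMATIC_PROVENANCE_NOTES: dict[str, str] = {
    "Confirmed somatic": (
        "Somatic origin confirmed by matched tumor-normal control sequencing."
    ),
    "Confirmed germline": (
        "Germline origin confirmed by matched tumor-normal control sequencing."
    ),
    "Unknown": (
        "Variant origin unverified: no matched normal control sequencing reported."
    ),
}

_EFFECT_NOTE_TEMPLATE = 'Source MVLD effect term: "{term}".'


def _load_two_column_table(name: str, path: str | Path | None) -> dict[str, str]:
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = resources.files("mvldkit.data").joinpath(name).read_text(encoding="utf-8")
    rows = list(csv.reader(text.splitlines(), delimiter="\t"))
    return {r[0]: r[1] for r in rows[1:] if r}


@lru_cache(maxsize=4)
def _bundled_field_map() -> tuple[FieldMapEntry, ...]:
    text = resources.files("mvldkit.data").joinpath("field_map.tsv").read_text("utf-8")
    return _parse_field_map(text)


def _parse_field_map(text: str) -> tuple[FieldMapEntry, ...]:
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    entries = []
    for row in reader:
        entries.append(
            FieldMapEntry(
                mvld_category=row["mvld_category"],
                mvld_field=row["mvld_field"],
                mapping_class=row["mapping_class"],
                civic_target=row.get("civic_target") or None,
                workaround_note=row.get("workaround_note") or None,
            )
        )
    return tuple(entries)


def field_map(table_path: str | Path | None = None) -> list[FieldMapEntry]:
    """The frozen MVLD → CIViC field mapping: 18 entries, one per field.

    All six Allele Descriptive fields are direct mappings; Somatic
    Classification, Variant Type, Biomarker Class, Effect and Level of
    Evidence are relatable (mapped with a documented workaround); the
    expert-opinion Sub-Level of Evidence has no CIViC analog.
    """
    if table_path is not None:
        return list(_parse_field_map(Path(table_path).read_text(encoding="utf-8")))
    return list(_bundled_field_map())


def map_effect_term(effect: str, table_path: str | Path | None = None) -> str:
    """Map one of the five MVLD effect terms onto the updated CIViC
    predictive clinical-significance vocabulary.

    Sensitive and Responsive collapse to the compound term
    Sensitivity/Response; Not-Responsive is subsumed by Resistance (the
    pre-update CIViC term was "Resistance or Non-Response"); Reduced
    Sensitivity carries over unchanged.
    """
    table = _load_two_column_table("effect_term_map.tsv", table_path)
    if effect not in table:
        raise VocabularyError(
            f"effect term {effect!r} is not in the five-term vocabulary {EFFECT_TERMS}"
        )
    return table[effect]


def map_prognostic_effect(effect: str, table_path: str | Path | None = None) -> str:
    """Supplementary mapping of the (optional) effect term for prognostic
    records onto {Better Outcome, Poor Outcome}; unmapped nuance belongs
    in the Evidence Statement text."""
    table = _load_two_column_table("prognostic_effect_map.tsv", table_path)
    if effect not in table:
        raise VocabularyError(
            f"effect term {effect!r} is not in the five-term vocabulary {EFFECT_TERMS}"
        )
    return table[effect]


def map_consequence(consequence: str) -> str:
    """Pass an MVLD Variant Consequence through to a CIViC variant type.

    The mapping is the identity on valid Sequence Ontology terms, after
    case and whitespace normalization; unknown terms raise
    :class:`VocabularyError` with a nearest-match suggestion.
    """
    normalized = normalize_so_term(consequence)
    if normalized not in so_terms():
        suggestion = nearest_so_term(consequence)
        hint = f"; did you mean {suggestion!r}?" if suggestion else ""
        raise VocabularyError(
            f"{consequence!r} is not a bundled Sequence Ontology term{hint}"
        )
    return normalized


def parse_cancer_type(cancer_type: str) -> Disease:
    """Split an MVLD cancer-type cell into name and optional DOID.

    The canonical inline form is ``"Melanoma [DOID:1909]"``; a bare name
    yields a disease with no ontology identifier.
    """
    text = cancer_type.strip()
    if text.endswith("]") and "[DOID:" in text:
        name, _, tail = text.rpartition("[DOID:")
        doid = tail[:-1].strip()
        if doid.isdigit():
            return Disease(name=name.strip(), doid=doid)
    return Disease(name=text, doid=None)


def format_cancer_type(disease: Disease) -> str:
    """Inverse of :func:`parse_cancer_type`."""
    if disease.doid:
        return f"{disease.name} [DOID:{disease.doid}]"
    return disease.name


def _variant_name(protein_sub: str) -> str:
    return protein_sub[2:] if protein_sub.startswith("p.") else protein_sub


def mvld_to_precuration(record: MVLDRecord) -> CivicPrecuration:
    """Transform a valid MVLD record into a CIViC precuration draft.

    The field map is applied entry by entry: Allele Descriptive and
    Interpretive fields populate the draft variant; each PMID yields one
    evidence stub pre-filled with disease, drugs, evidence type,
    direction, clinical significance and a templated statement carrying
    the somatic-classification provenance note (plus the original effect
    term, whose mapping is otherwise lossy); nonmappable values land in
    ``unmapped``. Records failing validation are rejected.
    """
    report = validate_mvld_record(record)
    if not report.is_valid:
        msgs = "; ".join(str(e) for e in report.errors)
        raise ValueError(f"MVLD record fails validation and cannot be harmonized: {msgs}")

    ad, ai, si = record.allele_descriptive, record.allele_interpretive, record.somatic_interpretive
    change = ad.dna_position
    start, stop = derived_coordinates(
        change.start, change.reference_allele, change.alternate_allele
    )
    variant = CivicVariant(
        variant_id=None,
        gene_symbol=ad.gene_name,
        name=_variant_name(ai.protein_sub_and_position),
        chromosome=ad.chromosome,
        start=start,
        stop=stop,
        reference_bases=change.reference_allele,
        variant_bases=change.alternate_allele,
        reference_build=ad.genome_build,
        representative_transcript=ad.refseq_transcript,
        variant_types=[map_consequence(ai.variant_consequence)],
        hgvs_expressions=[
            f"{ad.refseq_transcript}:{ai.dna_sub_and_position}",
            f"{ad.refseq_protein}:{ai.protein_sub_and_position}",
        ],
        allele_registry_id=None,
    )

    disease = parse_cancer_type(si.cancer_type)
    evidence_type = si.biomarker_class
    if evidence_type == "Predictive":
        direction = "Supports"
        significance = map_effect_term(si.effect)
    elif evidence_type == "Prognostic":
        direction = record.extensions["evidence_direction"]
        significance = map_prognostic_effect(si.effect) if si.effect else "N/A"
    else:  # Diagnostic
        direction = record.extensions["evidence_direction"]
        # diagnostic template default; the curator confirms per publication
        significance = "Positive"
    drugs = [si.therapeutic_context] if si.therapeutic_context.strip() else []
    level = si.level_of_evidence.split()[-1] if si.level_of_evidence else ""

    provenance = SOMATIC_PROVENANCE_NOTES[ai.somatic_classification]
    notes = [provenance]
    if si.effect:
        notes.append(_EFFECT_NOTE_TEMPLATE.format(term=si.effect))

    stubs = []
    for pmid in ai.pmids:
        statement = " ".join(
            [f"Precuration stub generated from an MVLD record for PMID {pmid}."] + notes
        )
        stubs.append(
            EvidenceItem(
                eid=None,
                variant_id=None,
                disease=disease,
                drugs=list(drugs),
                evidence_type=evidence_type,
                evidence_direction=direction,
                clinical_significance=significance,
                evidence_level=level,
                rating=None,
                pmid=pmid,
                statement=statement,
                status="submitted",
            )
        )

    return CivicPrecuration(
        variant=variant,
        evidence_stubs=stubs,
        amp=AmpClassification.parse(si.level_of_evidence) if si.level_of_evidence else None,
        unmapped={
            "sub_level_of_evidence": si.sub_level_of_evidence,
            "variant_type": ai.variant_type,
        },
    )


def precuration_field_audit(record: MVLDRecord, precuration: CivicPrecuration) -> dict[str, bool]:
    """Check, field by field, that every MVLD value is recoverable from
    the precuration (mapped field, statement note, or unmapped bucket).

    Returns a mapping over all 18 canonical fields; ``True`` means the
    value (or its documented transform) was found. Each check is an
    explicit per-field equality, independent of the mapping code path.
    """
    ad, ai, si = record.allele_descriptive, record.allele_interpretive, record.somatic_interpretive
    v, stubs = precuration.variant, precuration.evidence_stubs
    change = ad.dna_position
    start, stop = derived_coordinates(
        change.start, change.reference_allele, change.alternate_allele
    )
    disease = parse_cancer_type(si.cancer_type)

    def in_all_statements(text: str) -> bool:
        return bool(stubs) and all(text in s.statement for s in stubs)

    audit = {
        "genome_build": v.reference_build == ad.genome_build,
        "gene_name": v.gene_symbol == ad.gene_name,
        "chromosome": v.chromosome == ad.chromosome,
        "dna_position": (
            (v.start, v.stop, v.reference_bases, v.variant_bases)
            == (start, stop, change.reference_allele, change.alternate_allele)
        ),
        "refseq_transcript": v.representative_transcript == ad.refseq_transcript,
        "refseq_protein": any(
            e.startswith(ad.refseq_protein + ":") for e in v.hgvs_expressions
        ),
        "dna_sub_and_position": any(
            e.endswith(":" + ai.dna_sub_and_position) for e in v.hgvs_expressions
        ),
        "protein_sub_and_position": v.name == _variant_name(ai.protein_sub_and_position),
        "variant_type": precuration.unmapped.get("variant_type") == ai.variant_type,
        "variant_consequence": map_consequence(ai.variant_consequence) in v.variant_types,
        "somatic_classification": in_all_statements(
            SOMATIC_PROVENANCE_NOTES[ai.somatic_classification]
        ),
        "pmids": [s.pmid for s in stubs] == list(ai.pmids),
        "cancer_type": bool(stubs)
        and all(s.disease == disease for s in stubs),
        "biomarker_class": bool(stubs)
        and all(s.evidence_type == si.biomarker_class for s in stubs),
        "therapeutic_context": (
            not si.therapeutic_context.strip()
            or (bool(stubs) and all(si.therapeutic_context in s.drugs for s in stubs))
        ),
        "effect": (
            not si.effect
            or in_all_statements(_EFFECT_NOTE_TEMPLATE.format(term=si.effect))
        ),
        "level_of_evidence": (
            not si.level_of_evidence
            or precuration.amp == AmpClassification.parse(si.level_of_evidence)
        ),
        "sub_level_of_evidence": (
            precuration.unmapped.get("sub_level_of_evidence") == si.sub_level_of_evidence
        ),
    }
    assert set(audit) == set(CANONICAL_COLUMNS)
    return audit


def mapping_report(records: list[MVLDRecord]) -> dict:
    """Coverage summary for a batch of MVLD records.

    Reports per-field population counts and rates, and the number of
    populated values encountered per mapping class. Deterministic and
    order-independent.
    """
    entries = field_map()
    class_of = {e.mvld_field: e.mapping_class for e in entries}
    n = len(records)
    population = {f: 0 for f in CANONICAL_COLUMNS}
    class_counts = {"direct": 0, "relatable": 0, "nonmappable": 0}
    for rec in records:
        cols = rec.to_columns()
        for f in CANONICAL_COLUMNS:
            if cols[f] != "":
                population[f] += 1
                class_counts[class_of[f]] += 1
    return {
        "n_records": n,
        "field_population": {
            f: {"count": population[f], "rate": (population[f] / n) if n else 0.0}
            for f in CANONICAL_COLUMNS
        },
        "class_value_counts": class_counts,
    }
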