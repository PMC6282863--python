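"""MVLD (Minimum Variant Level Data) records: model, I/O and validation.

An MVLD record is a precuration ticket for one somatic SNV or small indel,
organized into exactly three field categories:

* **Allele Descriptive** — genomic identity: build, gene, chromosome, DNA
  position with VCF-style alleles, RefSeq transcript and protein.
* **Allele Interpretive** — coding/protein change strings, variant type and
  Sequence Ontology consequence, somatic classification, PubMed IDs.
* **Somatic Interpretive** — clinical content: cancer type, biomarker
  class, therapeutic context, effect, AMP level of evidence, and the
  expert-opinion sub-level.

The canonical flat serialization is an 18-column TSV (one column per
field; the DNA position column packs ``START:REF:ALT``) or a JSON array of
objects keyed by the three category names. Diagnostic/prognostic records
additionally carry an ``evidence_direction`` precuration extension, kept
outside the 18 core columns because MVLD itself leaves direction as open
text.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from pydantic import BaseModel, Field

from . import alleles
from .validation import ValidationReport
from .vocab import (
    AMP_CLASSIFICATION_STRINGS,
    BIOMARKER_CLASSES,
    CHROMOSOMES,
    EFFECT_TERMS,
    EVIDENCE_DIRECTIONS,
    GENOME_BUILDS,
    SOMATIC_CLASSIFICATIONS,
    nearest_so_term,
    so_terms,
)

__all__ = [
    "GenomicChange",
    "AlleleDescriptive",
    "AlleleInterpretive",
    "SomaticInterpretive",
    "MVLDRecord",
    "MVLDFormatError",
    "CANONICAL_COLUMNS",
    "COLUMN_CATEGORIES",
    "EXTENSION_COLUMNS",
    "read_mvld",
    "write_mvld",
    "validate_mvld_record",
]

#: Frozen inventory of the 18 canonical MVLD column names, in serialization
#: order: six Allele Descriptive, six Allele Interpretive, six Somatic
#: Interpretive.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "genome_build",
    "gene_name",
    "chromosome",
    "dna_position",
    "refseq_transcript",
    "refseq_protein",
    "dna_sub_and_position",
    "protein_sub_and_position",
    "variant_type",
    "variant_consequence",
    "somatic_classification",
    "pmids",
    "cancer_type",
    "biomarker_class",
    "therapeutic_context",
    "effect",
    "level_of_evidence",
    "sub_level_of_evidence",
)

COLUMN_CATEGORIES: dict[str, str] = {
    **{c: "Allele Descriptive" for c in CANONICAL_COLUMNS[:6]},
    **{c: "Allele Interpretive" for c in CANONICAL_COLUMNS[6:12]},
    **{c: "Somatic Interpretive" for c in CANONICAL_COLUMNS[12:]},
}

#: Recognized precuration-extension columns (outside the 18 core fields).
EXTENSION_COLUMNS: tuple[str, ...] = ("evidence_direction",)

_MAX_ALLELE_LEN = 50  # SNV/small-indel scope bound, in bases

_NM_RE = re.compile(r"^NM_\d+\.\d+$")
_NP_RE = re.compile(r"^NP_\d+\.\d+$")
_GENE_RE = re.compile(r"^[A-Z][A-Z0-9-]*$")
_ALLELE_RE = re.compile(r"^[ACGT]*$")


class MVLDFormatError(ValueError):
    """A serialized MVLD document violates the dialect (bad header, row)."""


class GenomicChange(BaseModel):
    """1-based start position with VCF-style reference/alternate alleles.

    Alleles are trimmed on ingest (shared anchor bases removed), so the
    representation is unique; the end coordinate is derived, not stored.
    """

    start: int
    reference_allele: str
    alternate_allele: str

    @classmethod
    def from_vcf_style(cls, start: int, ref: str, alt: str) -> "GenomicChange":
        start, ref, alt = alleles.trim(start, ref, alt)
        return cls(start=start, reference_allele=ref, alternate_allele=alt)

    @classmethod
    def parse(cls, cell: str) -> "GenomicChange":
        """Parse the packed TSV form ``START:REF:ALT``."""
        parts = cell.split(":")
        if len(parts) != 3:
            raise MVLDFormatError(
                f"dna_position cell {cell!r} is not in START:REF:ALT form"
            )
        try:
            start = int(parts[0])
        except ValueError:
            raise MVLDFormatError(f"dna_position start {parts[0]!r} is not an integer") from None
        return cls.from_vcf_style(start, parts[1].upper(), parts[2].upper())

    def packed(self) -> str:
        return f"{self.start}:{self.reference_allele}:{self.alternate_allele}"

    @property
    def stop(self) -> int:
        return alleles.derived_coordinates(
            self.start, self.reference_allele, self.alternate_allele
        )[1]


class AlleleDescriptive(BaseModel):
    genome_build: str
    gene_name: str
    chromosome: str
    dna_position: GenomicChange
    refseq_transcript: str
    refseq_protein: str


class AlleleInterpretive(BaseModel):
    dna_sub_and_position: str
    protein_sub_and_position: str
    variant_type: str
    variant_consequence: str
    somatic_classification: str
    pmids: list[str] = Field(default_factory=list)


class SomaticInterpretive(BaseModel):
    cancer_type: str
    biomarker_class: str
    therapeutic_context: str = ""
    effect: str = ""
    level_of_evidence: str = ""
    sub_level_of_evidence: str = ""


class MVLDRecord(BaseModel):
    """One precuration record: exactly the three MVLD field categories,
    plus recognized precuration extensions and a passthrough map for
    unknown input columns (retained verbatim, flagged as warnings)."""

    allele_descriptive: AlleleDescriptive
    allele_interpretive: AlleleInterpretive
    somatic_interpretive: SomaticInterpretive
    extensions: dict[str, str] = Field(default_factory=dict)
    passthrough: dict[str, str] = Field(default_factory=dict)

    def to_columns(self) -> dict[str, str]:
        """Flatten to the canonical 18 columns (strings, TSV dialect)."""
        ad, ai, si = self.allele_descriptive, self.allele_interpretive, self.somatic_interpretive
        return {
            "genome_build": ad.genome_build,
            "gene_name": ad.gene_name,
            "chromosome": ad.chromosome,
            "dna_position": ad.dna_position.packed(),
            "refseq_transcript": ad.refseq_transcript,
            "refseq_protein": ad.refseq_protein,
            "dna_sub_and_position": ai.dna_sub_and_position,
            "protein_sub_and_position": ai.protein_sub_and_position,
            "variant_type": ai.variant_type,
            "variant_consequence": ai.variant_consequence,
            "somatic_classification": ai.somatic_classification,
            "pmids": "|".join(ai.pmids),
            "cancer_type": si.cancer_type,
            "biomarker_class": si.biomarker_class,
            "therapeutic_context": si.therapeutic_context,
            "effect": si.effect,
            "level_of_evidence": si.level_of_evidence,
            "sub_level_of_evidence": si.sub_level_of_evidence,
        }

    @classmethod
    def from_columns(cls, row: dict[str, str]) -> "MVLDRecord":
        """Build a record from a flat column->cell mapping.

        Cells for the 18 canonical columns must all be present (empty
        string means absent); recognized extension columns go to
        ``extensions`` and anything else to ``passthrough``.
        """
        missing = [c for c in CANONICAL_COLUMNS if c not in row]
        if missing:
            raise MVLDFormatError(f"missing required column(s): {', '.join(missing)}")
        pmids = [p for p in row["pmids"].split("|") if p] if row["pmids"] else []
        extensions = {
            k: row[k] for k in EXTENSION_COLUMNS if k in row and row[k] != ""
        }
        passthrough = {
            k: v
            for k, v in row.items()
            if k not in CANONICAL_COLUMNS and k not in EXTENSION_COLUMNS and v != ""
        }
        return cls(
            allele_descriptive=AlleleDescriptive(
                genome_build=row["genome_build"],
                gene_name=row["gene_name"],
                chromosome=row["chromosome"],
                dna_position=GenomicChange.parse(row["dna_position"]),
                refseq_transcript=row["refseq_transcript"],
                refseq_protein=row["refseq_protein"],
            ),
            allele_interpretive=AlleleInterpretive(
                dna_sub_and_position=row["dna_sub_and_position"],
                protein_sub_and_position=row["protein_sub_and_position"],
                variant_type=row["variant_type"],
                variant_consequence=row["variant_consequence"],
                somatic_classification=row["somatic_classification"],
                pmids=pmids,
            ),
            somatic_interpretive=SomaticInterpretive(
                cancer_type=row["cancer_type"],
                biomarker_class=row["biomarker_class"],
                therapeutic_context=row["therapeutic_context"],
                effect=row["effect"],
                level_of_evidence=row["level_of_evidence"],
                sub_level_of_evidence=row["sub_level_of_evidence"],
            ),
            extensions=extensions,
            passthrough=passthrough,
        )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "tsv"


def read_mvld(path: str | Path, fmt: str | None = None) -> list[MVLDRecord]:
    """Read MVLD records from a TSV or JSON file, preserving input order.

    TSV: UTF-8, tab-separated, mandatory header using the canonical column
    names, ``|``-delimited multi-valued cells, empty string = absent.
    JSON: an array of objects keyed by the three category names.

    Unknown columns are retained on each record's ``passthrough`` map (and
    surfaced as warnings by :func:`validate_mvld_record`); a missing
    canonical column raises :class:`MVLDFormatError` naming it.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    text = path.read_text(encoding="utf-8")
    if fmt == "json":
        return _read_json(text)
    return _read_tsv(text)


def _read_tsv(text: str) -> list[MVLDRecord]:
    lines = text.splitlines()
    if not lines:
        raise MVLDFormatError("empty file: MVLD TSV requires a header row")
    header = lines[0].split("\t")
    missing = [c for c in CANONICAL_COLUMNS if c not in header]
    if missing:
        raise MVLDFormatError(f"missing required column(s): {', '.join(missing)}")
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if line == "":
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise MVLDFormatError(
                f"row {lineno}: expected {len(header)} cells, found {len(cells)}"
            )
        row = dict(zip(header, cells))
        try:
            records.append(MVLDRecord.from_columns(row))
        except MVLDFormatError as exc:
            raise MVLDFormatError(f"row {lineno}: {exc}") from None
    return records


def _read_json(text: str) -> list[MVLDRecord]:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MVLDFormatError(f"malformed JSON: {exc}") from None
    if not isinstance(data, list):
        raise MVLDFormatError("MVLD JSON must be an array of record objects")
    records = []
    for i, obj in enumerate(data):
        for category in ("allele_descriptive", "allele_interpretive", "somatic_interpretive"):
            if category not in obj:
                raise MVLDFormatError(f"record {i}: missing category {category!r}")
        try:
            change = obj["allele_descriptive"]["dna_position"]
            # re-trim defensively so hand-edited JSON also normalizes
            obj["allele_descriptive"] = dict(
                obj["allele_descriptive"],
                dna_position=GenomicChange.from_vcf_style(
                    int(change["start"]),
                    change["reference_allele"].upper(),
                    change["alternate_allele"].upper(),
                ),
            )
            records.append(MVLDRecord.model_validate(obj))
        except (KeyError, TypeError, ValueError) as exc:
            raise MVLDFormatError(f"record {i}: {exc}") from None
    return records


def write_mvld(
    records: list[MVLDRecord],
    path: str | Path,
    fmt: str | None = None,
    bypass_validation: bool = False,
) -> None:
    """Write records as TSV or JSON; the output re-reads losslessly.

    Records must pass :func:`validate_mvld_record` unless
    ``bypass_validation`` is set.
    """
    if not bypass_validation:
        for i, rec in enumerate(records):
            report = validate_mvld_record(rec)
            if not report.is_valid:
                msgs = "; ".join(str(e) for e in report.errors)
                raise ValueError(f"record {i} fails validation: {msgs}")
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        payload = []
        for rec in records:
            obj = rec.model_dump()
            if not obj["extensions"]:
                del obj["extensions"]
            if not obj["passthrough"]:
                del obj["passthrough"]
            payload.append(obj)
        path.write_text(
            json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
        )
        return
    ext_cols = sorted({k for r in records for k in r.extensions})
    extra_cols = sorted({k for r in records for k in r.passthrough})
    header = list(CANONICAL_COLUMNS) + ext_cols + extra_cols
    lines = ["\t".join(header)]
    for rec in records:
        row = rec.to_columns()
        row.update({k: rec.extensions.get(k, "") for k in ext_cols})
        row.update({k: rec.passthrough.get(k, "") for k in extra_cols})
        lines.append("\t".join(row[c] for c in header))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def validate_mvld_record(record: MVLDRecord) -> ValidationReport:
    """Apply every MVLD precuration rule; findings go into the report.

    Rules (identifiers are stable):

    * ``MVLD-R1`` — allele/accession/HGVS-string syntax
    * ``MVLD-R2`` — enumeration membership (build, classifications,
      consequence against the bundled SO list, effect vocabulary, AMP
      level-of-evidence strings)
    * ``MVLD-R3`` — Predictive biomarker class requires a therapeutic
      context and an effect
    * ``MVLD-R4`` — Diagnostic/Prognostic records require the
      ``evidence_direction`` precuration extension
    * ``MVLD-R5`` — SNV/small-indel scope: alleles at most 50 bases
    * ``MVLD-R6`` — reference and alternate alleles must differ
    * ``MVLD-R7`` — PMIDs are positive-integer strings
    * ``MVLD-W1`` (warning) — no PMIDs: acceptable for precuration only
    * ``MVLD-W2`` (warning) — unknown input columns passed through
    """
    rep = ValidationReport()
    ad, ai, si = record.allele_descriptive, record.allele_interpretive, record.somatic_interpretive

    # --- syntax (R1) ---
    if ad.chromosome not in CHROMOSOMES:
        rep.error("MVLD-R1", "allele_descriptive.chromosome",
                  f"chromosome {ad.chromosome!r} is not 1-22, X, Y or MT (no 'chr' prefix)")
    change = ad.dna_position
    if change.start < 1:
        rep.error("MVLD-R1", "allele_descriptive.dna_position",
                  f"position {change.start} is not a positive 1-based coordinate")
    for which, allele in (("reference", change.reference_allele),
                          ("alternate", change.alternate_allele)):
        if not _ALLELE_RE.match(allele):
            rep.error("MVLD-R1", "allele_descriptive.dna_position",
                      f"{which} allele {allele!r} contains non-ACGT characters")
    if not _GENE_RE.match(ad.gene_name):
        rep.error("MVLD-R1", "allele_descriptive.gene_name",
                  f"gene name {ad.gene_name!r} is not an uppercase HGNC-style symbol")
    if not _NM_RE.match(ad.refseq_transcript):
        rep.error("MVLD-R1", "allele_descriptive.refseq_transcript",
                  f"{ad.refseq_transcript!r} does not match versioned pattern NM_*.n")
    if not _NP_RE.match(ad.refseq_protein):
        rep.error("MVLD-R1", "allele_descriptive.refseq_protein",
                  f"{ad.refseq_protein!r} does not match versioned pattern NP_*.n")
    if not ai.dna_sub_and_position.startswith("c."):
        rep.error("MVLD-R1", "allele_interpretive.dna_sub_and_position",
                  f"{ai.dna_sub_and_position!r} is not HGVS c. syntax")
    if not ai.protein_sub_and_position.startswith("p."):
        rep.error("MVLD-R1", "allele_interpretive.protein_sub_and_position",
                  f"{ai.protein_sub_and_position!r} is not HGVS p. syntax")
    if not si.cancer_type.strip():
        rep.error("MVLD-R1", "somatic_interpretive.cancer_type", "cancer type is empty")

    # --- enumerations (R2) ---
    if ad.genome_build not in GENOME_BUILDS:
        rep.error("MVLD-R2", "allele_descriptive.genome_build",
                  f"genome build {ad.genome_build!r} not in {GENOME_BUILDS}")
    if ai.somatic_classification not in SOMATIC_CLASSIFICATIONS:
        rep.error("MVLD-R2", "allele_interpretive.somatic_classification",
                  f"{ai.somatic_classification!r} not in {SOMATIC_CLASSIFICATIONS}")
    if si.biomarker_class not in BIOMARKER_CLASSES:
        rep.error("MVLD-R2", "somatic_interpretive.biomarker_class",
                  f"{si.biomarker_class!r} not in {BIOMARKER_CLASSES}")
    if ai.variant_consequence not in so_terms():
        suggestion = nearest_so_term(ai.variant_consequence)
        hint = f"; did you mean {suggestion!r}?" if suggestion else ""
        rep.error("MVLD-R2", "allele_interpretive.variant_consequence",
                  f"{ai.variant_consequence!r} is not a bundled Sequence Ontology term{hint}")
    if si.effect and si.effect not in EFFECT_TERMS:
        rep.error("MVLD-R2", "somatic_interpretive.effect",
                  f"effect {si.effect!r} not in the five-term vocabulary {EFFECT_TERMS}")
    if si.level_of_evidence and si.level_of_evidence not in AMP_CLASSIFICATION_STRINGS:
        rep.error("MVLD-R2", "somatic_interpretive.level_of_evidence",
                  f"{si.level_of_evidence!r} is not a valid AMP classification "
                  f"(expected one of {AMP_CLASSIFICATION_STRINGS})")

    # --- biomarker-class cross-field rules (R3, R4) ---
    if si.biomarker_class == "Predictive":
        if not si.therapeutic_context.strip():
            rep.error("MVLD-R3", "somatic_interpretive.therapeutic_context",
                      "Predictive biomarker class requires a therapeutic context")
        if not si.effect.strip():
            rep.error("MVLD-R3", "somatic_interpretive.effect",
                      "Predictive biomarker class requires an effect term")
    if si.biomarker_class in ("Prognostic", "Diagnostic"):
        direction = record.extensions.get("evidence_direction", "")
        if not direction:
            rep.error("MVLD-R4", "extensions.evidence_direction",
                      f"{si.biomarker_class} records require an evidence direction "
                      "in the precuration extension")
        elif direction not in EVIDENCE_DIRECTIONS:
            rep.error("MVLD-R4", "extensions.evidence_direction",
                      f"direction {direction!r} not in {EVIDENCE_DIRECTIONS}")

    # --- scope and degeneracy (R5, R6) ---
    if (len(change.reference_allele) > _MAX_ALLELE_LEN
            or len(change.alternate_allele) > _MAX_ALLELE_LEN):
        rep.error("MVLD-R5", "allele_descriptive.dna_position",
                  f"allele longer than {_MAX_ALLELE_LEN} bases is outside the "
                  "SNV/small-indel scope")
    if change.reference_allele == change.alternate_allele:
        rep.error("MVLD-R6", "allele_descriptive.dna_position",
                  "reference and alternate alleles are identical after trimming")

    # --- PMIDs (R7 / W1) ---
    for pmid in ai.pmids:
        if not pmid.isdigit() or int(pmid) <= 0:
            rep.error("MVLD-R7", "allele_interpretive.pmids",
                      f"PMID {pmid!r} is not a positive-integer string")
    if not ai.pmids:
        rep.warning("MVLD-W1", "allele_interpretive.pmids",
                    "no PMIDs: acceptable in precuration, but workflow submission "
                    "requires at least one")

    # --- passthrough (W2) ---
    for col in sorted(record.passthrough):
        rep.warning("MVLD-W2", f"passthrough.{col}",
                    "unknown input column retained verbatim")
    return rep
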