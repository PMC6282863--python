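"""CIViC-side entities: variants, evidence items, assertions.

Includes the reader for CIViC-API-shaped JSON documents (read from disk;
no network), the per-entity validators, the genomic-HGVS builder used to
construct ClinGen Allele Registry lookup keys, and the offline registry
cache lookup. The JSON dialect is frozen in ``data/civic_schema.json``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field

from . import alleles
from .validation import ValidationReport
from .vocab import (
    AMP_LEVELS,
    AMP_TIERS,
    AMP_VALID_PAIRS,
    ASSERTION_STATUSES,
    ASSERTION_TYPES,
    EVIDENCE_DIRECTIONS,
    EVIDENCE_LEVELS,
    EVIDENCE_STATUSES,
    EVIDENCE_TYPES,
    GENOME_BUILDS,
    SIGNIFICANCE_BY_TYPE,
    is_significance_valid,
    so_terms,
)

__all__ = [
    "Disease",
    "CivicVariant",
    "EvidenceItem",
    "AmpClassification",
    "Assertion",
    "CivicBundle",
    "CivicFormatError",
    "ReferentialIntegrityError",
    "read_civic_json",
    "write_civic_json",
    "validate_evidence_item",
    "validate_assertion",
    "build_genomic_hgvs",
    "load_registry_cache",
    "lookup_allele_registry_id",
]


class CivicFormatError(ValueError):
    """Malformed CIViC JSON document."""


class ReferentialIntegrityError(CivicFormatError):
    """An entity references an identifier that does not exist."""


class Disease(BaseModel):
    name: str
    doid: Optional[str] = None


class CivicVariant(BaseModel):
    """A CIViC variant: gene-anchored coordinates plus ontology typing.

    Coordinates are 1-based fully closed; alleles are stored trimmed.
    ``variant_id`` is optional so precuration drafts (no identifier yet)
    can share the type.
    """

    variant_id: Optional[int] = None
    gene_symbol: str
    name: str
    chromosome: str
    start: int
    stop: int
    reference_bases: str
    variant_bases: str
    reference_build: str
    representative_transcript: str
    variant_types: list[str] = Field(default_factory=list)
    hgvs_expressions: list[str] = Field(default_factory=list)
    allele_registry_id: Optional[str] = None


class EvidenceItem(BaseModel):
    """One granular unit of clinical evidence drawn from a publication.

    ``eid``/``variant_id``/``rating`` are optional so that precuration
    stubs (drafts awaiting curator review) are representable; the
    validator treats a missing rating as a warning, a missing direction on
    diagnostic/prognostic evidence as an error.
    """

    eid: Optional[int] = None
    variant_id: Optional[int] = None
    disease: Disease
    drugs: list[str] = Field(default_factory=list)
    evidence_type: str
    evidence_direction: str = ""
    clinical_significance: str = ""
    evidence_level: str = ""
    rating: Optional[int] = None
    pmid: str = ""
    statement: str = ""
    status: str = "submitted"


class AmpClassification(BaseModel):
    """AMP somatic-interpretation tier and level.

    Only four combinations are admissible — Tier I Level A/B and
    Tier II Level C/D; :meth:`is_valid_pair` checks membership.
    """

    tier: str
    level: str

    def is_valid_pair(self) -> bool:
        return (self.tier, self.level) in AMP_VALID_PAIRS

    def __str__(self) -> str:
        return f"{self.tier} {self.level}"

    @classmethod
    def parse(cls, text: str) -> "AmpClassification":
        """Parse a combined string such as ``"Tier I Level A"``."""
        for tier in AMP_TIERS:
            for level in AMP_LEVELS:
                if text == f"{tier} {level}":
                    return cls(tier=tier, level=level)
        raise ValueError(f"{text!r} is not an AMP 'Tier X Level Y' string")


class Assertion(BaseModel):
    """A state-of-the-field summary built from evidence items for one
    variant-disease pair, carrying an AMP tier/level."""

    aid: int
    variant_id: int
    disease: Disease
    drugs: list[str] = Field(default_factory=list)
    assertion_type: str
    amp: AmpClassification
    clinical_significance: Optional[str] = None
    summary: str = ""
    description: str = ""
    evidence_ids: list[int] = Field(default_factory=list)
    status: str = "submitted"
    organization: Optional[str] = None


class CivicBundle(BaseModel):
    """Typed contents of one CIViC-API-shaped document."""

    variants: list[CivicVariant] = Field(default_factory=list)
    evidence_items: list[EvidenceItem] = Field(default_factory=list)
    assertions: list[Assertion] = Field(default_factory=list)
    issues: list[str] = Field(default_factory=list)

    def variant_by_id(self, variant_id: int) -> Optional[CivicVariant]:
        return next((v for v in self.variants if v.variant_id == variant_id), None)

    def evidence_by_id(self, eid: int) -> Optional[EvidenceItem]:
        return next((e for e in self.evidence_items if e.eid == eid), None)


def _assertion_from_obj(obj: dict) -> Assertion:
    obj = dict(obj)
    if "amp" not in obj:
        obj["amp"] = {"tier": obj.pop("amp_tier"), "level": obj.pop("amp_level")}
    return Assertion.model_validate(obj)


def _assertion_to_obj(a: Assertion) -> dict:
    obj = a.model_dump()
    amp = obj.pop("amp")
    obj["amp_tier"] = amp["tier"]
    obj["amp_level"] = amp["level"]
    return obj


def read_civic_json(path: str | Path, strict: bool = True) -> CivicBundle:
    """Read a CIViC-API-shaped JSON document into typed entities.

    The file must hold one object with ``variants``, ``evidence_items``
    and ``assertions`` arrays. Dangling references (evidence → variant,
    assertion → variant/evidence) raise :class:`ReferentialIntegrityError`
    naming both identifiers when ``strict`` (the default); with
    ``strict=False`` they are collected on ``bundle.issues`` so that
    deliberately broken fixtures can still be inspected and validated.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CivicFormatError(f"malformed JSON in {path}: {exc}") from None
    if not isinstance(data, dict):
        raise CivicFormatError("CIViC JSON must be a single top-level object")
    for key in ("variants", "evidence_items", "assertions"):
        if key not in data or not isinstance(data[key], list):
            raise CivicFormatError(f"CIViC JSON is missing the {key!r} array")
    try:
        bundle = CivicBundle(
            variants=[CivicVariant.model_validate(v) for v in data["variants"]],
            evidence_items=[EvidenceItem.model_validate(e) for e in data["evidence_items"]],
            assertions=[_assertion_from_obj(a) for a in data["assertions"]],
        )
    except (KeyError, ValueError) as exc:
        raise CivicFormatError(f"cannot parse CIViC JSON entities: {exc}") from None

    variant_ids = {v.variant_id for v in bundle.variants}
    eids = {e.eid for e in bundle.evidence_items}
    problems = []
    for e in bundle.evidence_items:
        if e.variant_id not in variant_ids:
            problems.append(
                f"evidence item {e.eid} references missing variant {e.variant_id}"
            )
    for a in bundle.assertions:
        if a.variant_id not in variant_ids:
            problems.append(f"assertion {a.aid} references missing variant {a.variant_id}")
        for eid in a.evidence_ids:
            if eid not in eids:
                problems.append(f"assertion {a.aid} references missing evidence item {eid}")
    if problems and strict:
        raise ReferentialIntegrityError("; ".join(problems))
    bundle.issues = problems
    return bundle


def write_civic_json(bundle: CivicBundle, path: str | Path) -> None:
    """Serialize a bundle back to the frozen JSON dialect (deterministic)."""
    payload = {
        "variants": [v.model_dump() for v in bundle.variants],
        "evidence_items": [e.model_dump() for e in bundle.evidence_items],
        "assertions": [_assertion_to_obj(a) for a in bundle.assertions],
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, ensure_ascii=False, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def validate_evidence_item(e: EvidenceItem) -> ValidationReport:
    """Apply evidence-item curation rules; findings go into the report.

    * ``EV-R1`` — evidence type membership
    * ``EV-R2`` — diagnostic/prognostic evidence requires a direction and a
      non-empty Evidence Statement; direction values are controlled
    * ``EV-R3`` — predictive evidence requires at least one drug
    * ``EV-R4`` — star rating within 1..5 when assigned
      (``EV-W1`` warning when unassigned, as on precuration stubs)
    * ``EV-R5`` — clinical significance compatible with the evidence type
    * ``EV-R6`` — evidence level A-E
    * ``EV-R7`` — PMID is a positive-integer string
    * ``EV-R8`` — status membership; ``EV-R9`` — variant types in SO list
    """
    rep = ValidationReport()
    if e.evidence_type not in EVIDENCE_TYPES:
        rep.error("EV-R1", "evidence_type",
                  f"{e.evidence_type!r} not in {EVIDENCE_TYPES}")
    if e.evidence_type in ("Prognostic", "Diagnostic"):
        if not e.evidence_direction:
            rep.error("EV-R2", "evidence_direction",
                      f"{e.evidence_type} evidence requires an evidence direction")
        if not e.statement.strip():
            rep.error("EV-R2", "statement",
                      f"{e.evidence_type} evidence requires an Evidence Statement")
    if e.evidence_direction and e.evidence_direction not in EVIDENCE_DIRECTIONS:
        rep.error("EV-R2", "evidence_direction",
                  f"direction {e.evidence_direction!r} not in {EVIDENCE_DIRECTIONS}")
    if e.evidence_type == "Predictive" and not e.drugs:
        rep.error("EV-R3", "drugs", "Predictive evidence requires at least one drug")
    if e.rating is None:
        rep.warning("EV-W1", "rating", "star rating not yet assigned")
    elif not 1 <= e.rating <= 5:
        rep.error("EV-R4", "rating", f"rating {e.rating} outside the 1..5 star range")
    if e.clinical_significance and not is_significance_valid(
        e.evidence_type, e.clinical_significance
    ):
        allowed = SIGNIFICANCE_BY_TYPE.get(e.evidence_type, ())
        rep.error("EV-R5", "clinical_significance",
                  f"significance {e.clinical_significance!r} is not valid for "
                  f"{e.evidence_type} evidence (allowed: {allowed})")
    if e.evidence_level and e.evidence_level not in EVIDENCE_LEVELS:
        rep.error("EV-R6", "evidence_level",
                  f"level {e.evidence_level!r} not in {EVIDENCE_LEVELS}")
    if not e.pmid or not e.pmid.isdigit():
        rep.error("EV-R7", "pmid", f"PMID {e.pmid!r} is not a positive-integer string")
    if e.status not in EVIDENCE_STATUSES:
        rep.error("EV-R8", "status", f"status {e.status!r} not in {EVIDENCE_STATUSES}")
    return rep


def validate_assertion(a: Assertion, evidence: list[EvidenceItem]) -> ValidationReport:
    """Apply assertion rules against the supplied evidence items.

    * ``AS-R1`` — AMP tier/level pair must be one of the four valid
      combinations (Tier I A/B, Tier II C/D)
    * ``AS-R2`` — at least one supporting evidence item
    * ``AS-R3`` — every referenced EID must resolve
    * ``AS-R4`` — all supporting evidence shares the assertion's variant
    * ``AS-R5`` — predictive assertions require at least one drug
    * ``AS-R6`` — assertion type is predictive/prognostic/diagnostic
    * ``AS-R7`` — clinical significance compatible with the type
    * ``AS-R8`` — status membership
    """
    rep = ValidationReport()
    if not a.amp.is_valid_pair():
        rep.error("AS-R1", "amp",
                  f"({a.amp.tier}, {a.amp.level}) is not a valid AMP combination; "
                  "valid pairs are Tier I Level A/B and Tier II Level C/D")
    if not a.evidence_ids:
        rep.error("AS-R2", "evidence_ids", "assertion has no supporting evidence items")
    by_eid = {e.eid: e for e in evidence}
    for eid in a.evidence_ids:
        e = by_eid.get(eid)
        if e is None:
            rep.error("AS-R3", "evidence_ids",
                      f"assertion {a.aid} references missing evidence item {eid}")
        elif e.variant_id != a.variant_id:
            rep.error("AS-R4", "evidence_ids",
                      f"evidence item {eid} is for variant {e.variant_id}, not the "
                      f"assertion's variant {a.variant_id}")
    if a.assertion_type == "Predictive" and not a.drugs:
        rep.error("AS-R5", "drugs", "Predictive assertions require at least one drug")
    if a.assertion_type not in ASSERTION_TYPES:
        rep.error("AS-R6", "assertion_type",
                  f"{a.assertion_type!r} not in {ASSERTION_TYPES} "
                  "(predisposing evidence is not asserted)")
    if a.clinical_significance and not is_significance_valid(
        a.assertion_type, a.clinical_significance
    ):
        rep.error("AS-R7", "clinical_significance",
                  f"significance {a.clinical_significance!r} is not valid for "
                  f"{a.assertion_type} assertions")
    if a.status not in ASSERTION_STATUSES:
        rep.error("AS-R8", "status", f"status {a.status!r} not in {ASSERTION_STATUSES}")
    return rep


def validate_variant(v: CivicVariant) -> ValidationReport:
    """Coordinate sanity and SO-typing checks for a CIViC variant."""
    rep = ValidationReport()
    if v.start > v.stop:
        rep.error("VA-R1", "start", f"start {v.start} exceeds stop {v.stop}")
    if v.reference_build not in GENOME_BUILDS:
        rep.error("VA-R2", "reference_build",
                  f"{v.reference_build!r} not in {GENOME_BUILDS}")
    for term in v.variant_types:
        if term not in so_terms():
            rep.error("VA-R3", "variant_types",
                      f"{term!r} is not a bundled Sequence Ontology term")
    return rep


def build_genomic_hgvs(v: CivicVariant) -> str:
    """Genomic HGVS string for a variant, e.g. ``NC_000007.13:g.140453136A>T``.

    Uses the bundled per-build chromosome → RefSeq accession table; alleles
    must already be trimmed (as they are everywhere in this package).
    Deterministic, and injective over distinct trimmed variants on the
    same build. Raises :class:`mvldkit.alleles.HgvsError` for unknown
    chromosome/build and ``DegenerateVariantError`` when ref == alt.
    """
    return alleles.format_genomic_hgvs(
        v.reference_build, v.chromosome, v.start, v.stop,
        v.reference_bases, v.variant_bases,
    )


def load_registry_cache(path: str | Path) -> dict[str, str]:
    """Load an offline allele-registry cache: two-column TSV (hgvs_key, caid)."""
    path = Path(path)
    cache: dict[str, str] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    for i, line in enumerate(lines):
        if not line or (i == 0 and line.startswith("hgvs_key")):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CivicFormatError(f"registry cache line {i + 1}: expected 2 columns")
        cache[parts[0]] = parts[1]
    return cache


def lookup_allele_registry_id(hgvs: str, cache: dict[str, str]) -> Optional[str]:
    """Resolve a genomic HGVS key to a canonical allele identifier (CAid).

    Purely a table lookup against the offline cache; an absent key returns
    ``None`` — an identifier is never fabricated.
    """
    return cache.get(hgvs)
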