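"""Controlled vocabularies shared across the MVLD, CIViC and ClinVar layers.

Everything here is either fixed by the data models (genome builds, AMP
tier/level pairs, evidence-type significance vocabularies) or loaded from a
small bundled table (Sequence Ontology consequence terms, chromosome RefSeq
accessions). Term tables that a curation group may legitimately wish to
amend (effect-term maps, ClinVar significance rendering) live in
:mod:`mvldkit.harmonize` / :mod:`mvldkit.clinvar` as editable TSV data.
"""

from __future__ import annotations

import csv
import difflib
from functools import lru_cache
from importlib import resources

GENOME_BUILDS = ("GRCh37", "GRCh38", "NCBI36")

CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

BIOMARKER_CLASSES = ("Predictive", "Prognostic", "Diagnostic")

# CIViC additionally records predisposing evidence; it is representable but
# excluded from assertion building and ClinVar export.
EVIDENCE_TYPES = ("Predictive", "Prognostic", "Diagnostic", "Predisposing")

ASSERTION_TYPES = BIOMARKER_CLASSES

SOMATIC_CLASSIFICATIONS = ("Confirmed somatic", "Confirmed germline", "Unknown")

EVIDENCE_DIRECTIONS = ("Supports", "Does not support")

EVIDENCE_LEVELS = ("A", "B", "C", "D", "E")

EVIDENCE_STATUSES = ("submitted", "accepted", "rejected")

ASSERTION_STATUSES = ("submitted", "accepted")

# The five-term somatic effect vocabulary used by the MVLD Somatic
# Interpretive "Effect" field.
EFFECT_TERMS = (
    "Resistant",
    "Responsive",
    "Not-Responsive",
    "Sensitive",
    "Reduced Sensitivity",
)

# Per-evidence-type clinical-significance vocabularies, after the term
# update that renamed Sensitivity -> Sensitivity/Response, restricted
# "Resistance or Non-Response" -> Resistance, and added Reduced Sensitivity.
SIGNIFICANCE_BY_TYPE: dict[str, tuple[str, ...]] = {
    "Predictive": (
        "Sensitivity/Response",
        "Resistance",
        "Reduced Sensitivity",
        "Adverse Response",
        "N/A",
    ),
    "Prognostic": ("Better Outcome", "Poor Outcome", "N/A"),
    "Diagnostic": ("Positive", "Negative"),
    # Predisposing evidence exists in CIViC but is out of scope for the
    # assertion/export workflow; it carries no significance vocabulary here.
    "Predisposing": ("N/A",),
}

AMP_TIERS = ("Tier I", "Tier II")
AMP_LEVELS = ("Level A", "Level B", "Level C", "Level D")

# The only admissible AMP tier/level combinations, Tier I Level A through
# Tier II Level D.
AMP_VALID_PAIRS = frozenset(
    {
        ("Tier I", "Level A"),
        ("Tier I", "Level B"),
        ("Tier II", "Level C"),
        ("Tier II", "Level D"),
    }
)

AMP_CLASSIFICATION_STRINGS = tuple(
    f"{tier} {level}" for tier, level in sorted(AMP_VALID_PAIRS)
)


def is_significance_valid(evidence_type: str, term: str) -> bool:
    """Total type x term compatibility predicate.

    Every (evidence_type, term) pair is classified: unknown evidence types
    and terms outside the type's vocabulary are invalid, members are valid.
    """
    return term in SIGNIFICANCE_BY_TYPE.get(evidence_type, ())


def _read_data_text(name: str) -> str:
    return resources.files("mvldkit.data").joinpath(name).read_text(encoding="utf-8")


@lru_cache(maxsize=1)
def so_terms() -> frozenset[str]:
    """Bundled Sequence Ontology consequence term list."""
    terms = set()
    for line in _read_data_text("so_terms.txt").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.add(line)
    return frozenset(terms)


def normalize_so_term(term: str) -> str:
    """Case- and whitespace-normalize a consequence term to SO style."""
    return "_".join(term.strip().lower().split()).replace("__", "_")


def nearest_so_term(term: str) -> str | None:
    """Closest bundled SO term to ``term``, for error suggestions."""
    matches = difflib.get_close_matches(normalize_so_term(term), sorted(so_terms()), n=1)
    return matches[0] if matches else None


@lru_cache(maxsize=1)
def chromosome_accessions() -> dict[tuple[str, str], str]:
    """(build, chromosome) -> versioned RefSeq NC_ accession."""
    table: dict[tuple[str, str], str] = {}
    reader = csv.DictReader(_read_data_text("chrom_accessions.tsv").splitlines(), delimiter="\t")
    for row in reader:
        table[(row["build"], row["chromosome"])] = row["accession"]
    return table
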