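# Methods

## The problem

Somatic cancer variant knowledge moves between three representations:
MVLD (a minimal precuration format used by ClinGen somatic curators),
CIViC (an open knowledgebase whose evidence items and AMP-tiered
assertions structure the published literature), and ClinVar (which accepts
flat submission sheets). This package models all three, the mappings
between them, and the validation rules each imposes. No statistical
estimation is involved; the guarantees are structural (frozen mappings,
controlled vocabularies, lossless serialization) and behavioral
(validators that find exactly the defects present).

## Data model and conventions

**Coordinates** are 1-based and fully closed. **Alleles** are given
VCF-style and trimmed on ingest: shared suffix bases are removed first,
then shared prefix bases with the start advanced, so every small variant
has a unique representation. After trimming, a substitution has equal
single-base (or multi-base, for delins) alleles, a pure deletion has an
empty alternate spanning `start..stop`, and a pure insertion has an empty
reference placed between flanking bases `start` and `stop = start + 1`.
The SNV/small-indel scope is enforced as *allele length ≤ 50 bases*, the
conventional small-indel bound; longer events are rejected with a scope
error rather than exported incorrectly.

**The 18-column MVLD inventory** is frozen in `mvld.CANONICAL_COLUMNS`:
six fields per category. "DNA position" is one field serialized as
`START:REF:ALT`, keeping the six-field Allele Descriptive inventory while
carrying the alleles needed for HGVS and export; the end coordinate is
derived from the trimmed allele lengths. The evidence direction that
diagnostic/prognostic precuration requires is carried in a recognized
*extension* column (`evidence_direction`) outside the core 18, because
MVLD itself leaves direction as open text. Unknown input columns are never
dropped: they land in a passthrough map and surface as warnings.

**Validation** is report-based: validators return every finding with a
stable rule identifier and severity instead of raising on the first
problem. An entity is valid iff it has no error-severity finding;
warnings (missing PMIDs in precuration, unrated evidence stubs,
passthrough columns) do not block it. Validation of a record depends only
on that record, so results are deterministic and order-independent.

## The harmonization mapping

The MVLD→CIViC field map ships as an editable TSV
(`data/field_map.tsv`) with exactly one entry per canonical field and a
three-class taxonomy:

- *direct* (12 entries, including all six Allele Descriptive fields) — a
  CIViC field accepts the value unchanged;
- *relatable* (5) — a documented workaround carries the intent: somatic
  classification becomes a fixed provenance sentence in every Evidence
  Statement; the free-text variant type is subsumed by the Sequence
  Ontology consequence and retained verbatim; biomarker class is realized
  as the evidence type; the effect term maps through the five-term table;
  the AMP level of evidence applies at assertion level;
- *nonmappable* (1) — the expert-opinion sub-level of evidence has no
  CIViC analog and is retained verbatim in the precuration's `unmapped`
  bucket.

The **effect-term map** is total on its five-term domain
{Resistant, Responsive, Not-Responsive, Sensitive, Reduced Sensitivity}:
Sensitive and Responsive collapse to the compound term
Sensitivity/Response; Not-Responsive maps to Resistance because the
pre-update term "Resistance or Non-Response" subsumed non-response, and
the renamed term inherits that coverage — this is the one genuinely open
arrow in the mapping, so it lives in an editable data table
(`data/effect_term_map.tsv`) rather than code. The mapping is lossy by
design (5 terms onto a smaller target), so the original effect term is
always appended to stub statements as a fixed sentence, which is also
what makes the conservation property checkable. A supplementary table
maps effect terms for prognostic records onto {Better Outcome, Poor
Outcome}; diagnostic stubs default to Positive as a template value the
curator confirms per publication, with the direction taken from the
precuration extension.

**Precuration generation** (`mvld_to_precuration`) refuses invalid
records, then emits a draft CIViC variant (no identifiers, registry ID
unresolved) plus one evidence stub per PMID. Stubs pass evidence
validation as drafts: their only open findings are warnings for the
curator content that cannot be derived (the star rating). The
`precuration_field_audit` helper checks, per field and with explicit
equalities independent of the mapping loop, that every MVLD value is
recoverable from the output — mapped field, statement note, or unmapped
bucket.

## HGVS and registry linkage

Genomic HGVS strings are built from a bundled (build, chromosome) →
versioned RefSeq `NC_` accession table covering GRCh37 and GRCh38
(chromosomes 1–22, X, Y, MT). Substitutions render as `g.POSREF>ALT`,
deletions as `g.START_STOPdel` (single-base: `g.POSdel`), insertions as
`g.START_STOPins SEQ` on the flanking-base convention, and other length
changes as delins. The builder is deterministic and injective over
distinct trimmed variants on one build, which is what makes the strings
usable as allele-registry lookup keys. NCBI36 is representable in the
data model but has no accession table entry; building an HGVS key for it
is a lookup error. Registry resolution is strictly an offline cache
lookup (two-column TSV `hgvs_key → CAid`); an absent key yields no
identifier — a CAid is never fabricated. Live registration is out of
scope.

## ClinVar export

The submission sheet is a pinned 22-column UTF-8 TSV dialect
(`data/clinvar_layout.tsv`); ClinVar's real template is a versioned
workbook, so one text dialect is frozen and documented instead of
tracking template drift. Columns partition into exactly three generation
classes — 8 variant-direct (coordinates, alleles, assembly, genomic
HGVS), 8 assertion-mapped, 6 procedural — and exactly two
assertion-mapped columns (Condition ID type/value) carry the needs-logic
flag: with a Disease Ontology ID the type is `DOID` and the value the
bare numeral; without one, both stay empty and the preferred condition
name alone identifies the condition.

Significance rendering: predictive assertions become ClinVar
"drug response" with the drugs in the drug-response-condition column;
prognostic/diagnostic assertions render through an editable rule table
keyed by (assertion type, CIViC significance), defaulting to ClinVar's
"other"/"association" catch-alls because ClinVar's germline-centric
vocabulary has no direct somatic outcome terms — the table is data
precisely so a submitting group can revise it. Procedural constants:
allele origin `somatic`, affected status `yes`, collection method
`curation`, local ID `CIViC:AID<n>`, and the AMP guidelines citation
`PMID:27993330`. Citations are the deduplicated ascending PMIDs of the
supporting evidence items. Export is deterministic — identical inputs
give byte-identical sheets — and every row passes an internal schema
check before it is considered exportable. Predisposing evidence is
representable but excluded from assertion building and export.

## Synthetic data

The generator (`mvldkit.fixtures`) emulates the inputs of the workflow:
MVLD records aligned with CIViC variants (SNVs 70%, deletions 15%,
insertions 15%, positions uniform on 1e5–2e8, builds split evenly between
GRCh37 and GRCh38 by default), three evidence items per variant cycling
through the predictive/prognostic/diagnostic types with
vocabulary-consistent significances, ratings 1–5 and synthetic PMIDs,
and one AMP-classified assertion per variant up to the configured count.
Gene, drug and disease names come from small bundled lists; the disease
list contains DOID-bearing and DOID-free entries so both condition-ID
branches are exercised. With a positive `edge_case_rate`, that fraction
of MVLD records, evidence items and assertions each receive exactly one
labeled defect (missing therapeutic context or direction, oversized
allele, rating out of range, incompatible significance, invalid AMP
pair, dangling evidence reference); variants stay clean so
coordinate-derived products remain usable. The manifest's labels are the
ground truth that validator tests compare against. Generation is fully
deterministic under a seed, to the byte.

What the generator does *not* emulate: real literature text or PMIDs,
realistic gene–disease–drug co-occurrence, transcript-accurate c./p.
strings, or bucket-style CIViC variants. Passing tests therefore show
that the mechanics (validation, mapping, export) are correct on
well-formed and labeled-defective data, not that real curation input is
clean.

## Problem sizes and numerical choices

The standard check sizes are 500 entities (100 variants, 300 evidence
items, 100 assertions) at a 20% defect rate for generator/validator
agreement, and 1,000 records (18,000 field checks) for the
information-conservation audit; both complete in well under a second.
There is no floating-point tolerance anywhere: every comparison is exact
(strings, integers, byte-identity of files). Ties and degenerate inputs
are handled explicitly — identical ref/alt alleles are a degenerate
variant error, empty disease names an export error, header-only files
legal empty inputs.

## Known limitations

- The ClinVar dialect is pinned; real submissions require mapping onto
  the current ClinVar workbook version.
- The prognostic effect table and the ClinVar significance table encode
  pragmatic defaults for vocabularies the source standards leave open;
  both are shipped as editable data.
- The Sequence Ontology list is a curated SNV/indel-relevant subset, not
  the full ontology.
- HGVS normalization is trimming only; left-alignment against a
  reference sequence window is not performed (no reference genome is
  bundled), so two differently-anchored descriptions of the same repeat
  indel can map to different keys.
- Live CIViC API access, allele-registry registration, and ClinVar
  upload are out of scope by design.
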