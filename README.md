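# mvldkit

Interoperability tooling for somatic cancer variant curation: validate
**MVLD** (Minimum Variant Level Data) precuration records, harmonize them
into **CIViC**-shaped curation drafts, model AMP-tiered **assertions**, and
transform accepted assertions into **ClinVar**-compliant submission sheets.
Everything is file-based and offline — CIViC-API-shaped JSON is read from
disk, and ClinGen Allele Registry identifiers resolve against a local
cache.

## Who this is for

Curation groups that precurate somatic variants in the MVLD format (an
18-field structure in three categories: Allele Descriptive, Allele
Interpretive, Somatic Interpretive) and publish their interpretations
through CIViC and ClinVar. The package automates the mechanical parts of
that workflow — format validation, field mapping, and submission-sheet
generation — while leaving evidence judgment to curators.

## What it implements

- **MVLD model** (`mvldkit.mvld`) — the 18-column record (TSV/JSON
  dialects), lossless round-trip I/O, and a rule-based validator
  (`MVLD-R1`…`R7`): allele syntax, controlled vocabularies, the
  Predictive ⇒ therapeutic-context+effect rule, the diagnostic/prognostic
  evidence-direction requirement, and the SNV/small-indel scope bound
  (alleles ≤ 50 bp, trimmed on ingest).
- **CIViC model** (`mvldkit.civic`) — variants, evidence items and
  assertions with their controlled vocabularies; per-type
  clinical-significance compatibility; the AMP tier/level pair rule
  (exactly Tier I A/B and Tier II C/D validate); a genomic HGVS builder
  (`NC_000007.13:g.140453136A>T`) over a bundled per-build chromosome
  accession table; offline allele-registry lookup.
- **Harmonizer** (`mvldkit.harmonize`) — the frozen 18-entry MVLD→CIViC
  field map (direct / relatable / nonmappable), the five-term effect
  mapping onto the updated clinical-significance vocabulary (Sensitive and
  Responsive collapse to Sensitivity/Response), and
  `mvld_to_precuration`, which emits one evidence stub per PMID without
  losing any field value.
- **ClinVar export** (`mvldkit.clinvar`) — a frozen 22-column submission
  sheet whose columns partition into three generation classes
  (variant-direct, assertion-mapped, procedural; exactly two columns need
  condition-ID logic), plus deterministic TSV writing/reading.
- **Fixtures** (`mvldkit.fixtures`) — a seeded generator of MVLD/CIViC
  data with ground-truth labels for deliberately invalid entities, and a
  predictive worked example (assertion AID 5).

## Worked example

The bundled worked example is a BRAF V600E-like predictive record
(melanoma, dabrafenib sensitivity, Tier I Level A) with three supporting
evidence items. End to end from the shell:

```
$ mvldkit validate demo_mvld.json
0 error(s)
$ mvldkit mvld2civic demo_mvld.json demo_precuration.json
1 precuration(s), 3 evidence stub(s) written
$ mvldkit civic2clinvar demo_civic.json demo_submission.tsv \
      --organization "ClinGen Somatic WG"
exported 1 row(s), rejected 0 assertion(s)
```

Selected columns of the exported sheet:

```
Local ID    Condition ID type  Condition ID value  Clinical significance  Drug response condition  Citations
CIViC:AID5  DOID               1909                drug response          Dabrafenib               10000001|10000002|10000003
```

The local ID follows the `CIViC:AID<n>` convention; the condition resolves
through the Disease Ontology branch of the condition-ID logic; a
predictive assertion renders as ClinVar "drug response" with the drug
carried in the drug-response condition column; citations are the
deduplicated, ascending PMIDs of the supporting evidence items (synthetic
integers here). The same pipeline is available as library calls
(`mvld_to_precuration`, `assertion_to_row`, `write_submission`).

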