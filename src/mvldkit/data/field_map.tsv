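mvld_category	mvld_field	mapping_class	civic_target	workaround_note
Allele Descriptive	genome_build	direct	variant.reference_build
Allele Descriptive	gene_name	direct	variant.gene_symbol
Allele Descriptive	chromosome	direct	variant.chromosome
Allele Descriptive	dna_position	direct	variant.start/stop/reference_bases/variant_bases
Allele Descriptive	refseq_transcript	direct	variant.representative_transcript
Allele Descriptive	refseq_protein	direct	variant.hgvs_expressions
Allele Interpretive	dna_sub_and_position	direct	variant.hgvs_expressions
Allele Interpretive	protein_sub_and_position	direct	variant.name
Allele Interpretive	variant_type	relatable	variant.variant_types	No direct CIViC analog; the Sequence Ontology consequence carries variant typing and the free-text category is retained verbatim for the curator.
Allele Interpretive	variant_consequence	direct	variant.variant_types
Allele Interpretive	somatic_classification	relatable	evidence.statement	CIViC does not require matched-normal confirmation; control sequencing detail is recorded as a provenance note in the CIViC Evidence Statement.
Allele Interpretive	pmids	direct	evidence.pmid
Somatic Interpretive	cancer_type	direct	evidence.disease
Somatic Interpretive	biomarker_class	relatable	evidence.evidence_type	Biomarker class is realized as the CIViC evidence type paired with an evidence direction and clinical significance, not as a standalone field.
Somatic Interpretive	therapeutic_context	direct	evidence.drugs
Somatic Interpretive	effect	relatable	evidence.clinical_significance	Five effect terms map onto the updated clinical-significance vocabulary; Sensitive and Responsive collapse to Sensitivity/Response and residual nuance is added to the Evidence Statement.
Somatic Interpretive	level_of_evidence	relatable	assertion.amp	The AMP tier and level are applied on the assertion assembled from the record's evidence items, not on a single evidence item.
Somatic Interpretive	sub_level_of_evidence	nonmappable		Expert opinion has no analog in the CIViC data model; retained verbatim in the unmapped bucket for the curator.
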