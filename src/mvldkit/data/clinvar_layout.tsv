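column_name	field_class	source	needs_logic
Local ID	procedural	rule:local_id	0
Gene symbol	variant_direct	variant.gene_symbol	0
Chromosome	variant_direct	variant.chromosome	0
Start	variant_direct	variant.start	0
Stop	variant_direct	variant.stop	0
Reference allele	variant_direct	variant.reference_bases	0
Alternate allele	variant_direct	variant.variant_bases	0
Assembly	variant_direct	variant.reference_build	0
HGVS	variant_direct	variant.genomic_hgvs	0
Condition ID type	assertion_mapped	assertion.disease.doid	1
Condition ID value	assertion_mapped	assertion.disease.doid	1
Preferred condition name	assertion_mapped	assertion.disease.name	0
Clinical significance	assertion_mapped	assertion.assertion_type/clinical_significance	0
Drug response condition	assertion_mapped	assertion.drugs	0
Allele origin	procedural	rule:constant_somatic	0
Affected status	procedural	rule:constant_yes	0
Collection method	procedural	rule:constant_curation	0
Assertion criteria citation	procedural	rule:amp_guidelines_citation	0
Assertion criteria method	procedural	rule:amp_guidelines_method	0
Citations	assertion_mapped	assertion.evidence_ids->evidence.pmid	0
Comment	assertion_mapped	assertion.summary	0
Attribution	assertion_mapped	assertion.organization	0
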