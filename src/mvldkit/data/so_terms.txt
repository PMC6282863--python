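# Sequence Ontology consequence terms accepted for MVLD variant_consequence
# and CIViC variant_types. One term per line; '#' lines are comments.
# Curated subset covering SNV / small-indel consequences.
missense_variant
synonymous_variant
stop_gained
stop_lost
stop_retained_variant
start_lost
initiator_codon_variant
frameshift_variant
frameshift_truncation
frameshift_elongation
inframe_insertion
inframe_deletion
inframe_indel
conservative_inframe_insertion
conservative_inframe_deletion
disruptive_inframe_insertion
disruptive_inframe_deletion
protein_altering_variant
coding_sequence_variant
splice_donor_variant
splice_acceptor_variant
splice_region_variant
exon_loss_variant
transcript_ablation
transcript_amplification
5_prime_UTR_variant
3_prime_UTR_variant
intron_variant
upstream_gene_variant
downstream_gene_variant
intergenic_variant
regulatory_region_variant
TF_binding_site_variant
non_coding_transcript_exon_variant
non_coding_transcript_variant
incomplete_terminal_codon_variant
NMD_transcript_variant
mature_miRNA_variant
gain_of_function_variant
loss_of_function_variant
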