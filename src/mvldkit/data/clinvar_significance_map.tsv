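assertion_type	civic_significance	clinvar_significance
Prognostic	Better Outcome	other
Prognostic	Poor Outcome	other
Prognostic	N/A	other
Diagnostic	Positive	association
Diagnostic	Negative	other
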