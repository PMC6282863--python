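effect_term	prognostic_significance
Resistant	Poor Outcome
Responsive	Better Outcome
Not-Responsive	Poor Outcome
Sensitive	Better Outcome
Reduced Sensitivity	Poor Outcome
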