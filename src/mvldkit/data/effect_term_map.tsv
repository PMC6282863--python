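effect_term	civic_significance
Resistant	Resistance
Responsive	Sensitivity/Response
Not-Responsive	Resistance
Sensitive	Sensitivity/Response
Reduced Sensitivity	Reduced Sensitivity
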