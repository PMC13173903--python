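RPS	recombination-proficiency: negated sum of scaled expression of four DNA-repair genes	RIF1	PARI	RAD51	XRCC5
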