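gene_id	subgroup
Gabbr1	GABA_B
Gabbr2	GABA_B
Grm1	mGluR
Grm5	mGluR
Grm8	mGluR
Chrm1	muscarinic
Chrm2	muscarinic
Drd1	dopamine
Drd2	dopamine
Htr1a	serotonin
Htr2a	serotonin
Adra1a	adrenergic
Adrb1	adrenergic
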