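gene_id	subgroup
Scn1a	alpha
Scn2a	alpha
Scn3a	alpha
Scn8a	alpha
Scn9a	alpha
Scn1b	beta
Scn2b	beta
Scn3b	beta
Scn4b	beta
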