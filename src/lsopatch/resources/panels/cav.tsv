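gene_id	subgroup
Cacna1a	alpha
Cacna1b	alpha
Cacna1c	alpha
Cacna1d	alpha
Cacna1e	alpha
Cacna1g	alpha
Cacna1h	alpha
Cacna2d1	alpha2delta
Cacna2d2	alpha2delta
Cacna2d3	alpha2delta
Cacnb1	beta
Cacnb2	beta
Cacnb3	beta
Cacnb4	beta
Cacng2	gamma
Cacng4	gamma
Cacng5	gamma
Cacng7	gamma
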