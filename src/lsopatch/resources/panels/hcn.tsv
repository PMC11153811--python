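gene_id	subgroup
Hcn1	alpha
Hcn2	alpha
Hcn3	alpha
Hcn4	alpha
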