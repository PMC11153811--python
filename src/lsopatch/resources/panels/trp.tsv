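gene_id	subgroup
Trpc1	TRPC
Trpc3	TRPC
Trpm2	TRPM
Trpm3	TRPM
Trpm4	TRPM
Trpm7	TRPM
Mcoln1	TRPML
Trpv1	TRPV
Pkd2l2	TRPP
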