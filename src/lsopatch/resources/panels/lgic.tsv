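gene_id	subgroup
Gria1	AMPA
Gria2	AMPA
Gria3	AMPA
Gria4	AMPA
Grik1	kainate
Grik2	kainate
Grik5	kainate
Grin1	NMDA
Grin2a	NMDA
Grin2b	NMDA
Gabra1	GABA_A
Gabrb2	GABA_A
Gabrg2	GABA_A
Glra1	glycine
Glrb	glycine
Chrna4	nicotinic
Chrna7	nicotinic
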