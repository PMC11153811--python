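gene_id	subgroup
Slc17a6	glutamatergic
Slc6a5	glycinergic
Gad2	GABAergic
Ddc	dopaminergic
Chat	cholinergic
Calca	peptidergic
Ucn	peptidergic
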