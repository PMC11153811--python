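gene_id	subgroup
Kcna1	alpha
Kcna2	alpha
Kcna4	alpha
Kcna6	alpha
Kcnb1	alpha
Kcnb2	alpha
Kcnc1	alpha
Kcnc2	alpha
Kcnc3	alpha
Kcnc4	alpha
Kcnd1	alpha
Kcnd2	alpha
Kcnd3	alpha
Kcnq2	alpha
Kcnq3	alpha
Kcnq5	alpha
Kcnh1	alpha
Kcnh7	alpha
Kcnab1	regulatory
Kcnab2	regulatory
Kcnab3	regulatory
Kcne2	regulatory
Kcnip1	regulatory
Kcnip2	regulatory
Kcnip3	regulatory
Kcnip4	regulatory
Kcng4	regulatory
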