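genotype	condition	replicate	germinated	total
Col0	NaCl	1	45	75
Col0	NaCl	2	48	75
Col0	NaCl	3	43	75
ihpRNA	NaCl	1	60	75
ihpRNA	NaCl	2	63	75
ihpRNA	NaCl	3	58	75
FD792	NaCl	1	20	75
FD792	NaCl	2	18	75
FD792	NaCl	3	24	75
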