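# Bundled RR-TZF spacing grammars (anchor-spacer mini-language)
CCCH1_canonical	C-X(7,8)-C-X5-C-X3-H
CCCH1_general	C-X(5,20)-C-X5-C-X3-H
CCCH2	C-X5-C-X4-C-X3-H
CCCH2_variant_a	C-X4-C-X4-C-X3-H
CCCH2_variant_b	C-X7-C-X4-C-X3-H
CHCH	C-X5-H-X4-C-X3-H
SIGNATURE	K-X3-C-X5-H-X4-C-X3-H-X6-R-R-X6-Y-X4-C-X(7,8)-C-X5-C-X3-H-X2-F-E-X3-H-P-X7-C-X5-C-X4-C-F-F-A-H
ATYPICAL_OVERLAP	C-X12-C-X10-C-X3-H
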