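gene	group	bio_rep	tech_rep	ct
TdTZF1A	dry_seed	1	1	24.1
TdTZF1A	dry_seed	1	2	24.3
TdTZF1A	dry_seed	2	1	24.0
TdTZF1A	dry_seed	2	2	24.2
TdTZF1A	salt_6h	1	1	22.9
TdTZF1A	salt_6h	1	2	23.1
TdTZF1A	salt_6h	2	1	23.0
TdTZF1A	salt_6h	2	2	23.2
Td17S1	dry_seed	1	1	18.0
Td17S1	dry_seed	1	2	18.1
Td17S1	dry_seed	2	1	18.0
Td17S1	dry_seed	2	2	17.9
Td17S1	salt_6h	1	1	18.1
Td17S1	salt_6h	1	2	18.0
Td17S1	salt_6h	2	1	17.9
Td17S1	salt_6h	2	2	18.0
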