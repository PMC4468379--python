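protein_id	domain	start	end
p1	ANK	10	42
p1	ANK	43	75
p2	TZF	5	30
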