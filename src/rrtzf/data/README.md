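# Bundled data

- `rr_tzf_grammars` — the spacing-grammar definitions of the RR-TZF
  domain vocabulary (CHCH motif, first/second CCCH domains and their
  variants, the full family signature) in the package's anchor-spacer
  mini-language. Loaded by `rrtzf.motif_grammar.load_grammars`.

- `synthetic_exemplars.fasta` — **synthetic** reference exemplars, one per
  group label (I, II×{IIa, IIb}, III, IV, V), generated deterministically
  by `rrtzf.synth.reference_set_for_seed(7)`. They are planted-architecture
  stand-ins so that classification runs without any database download;
  replace them with curated Arabidopsis reference proteins (AtTZF1-11) for
  real analyses. Header tags `group=` / `subgroup=` carry the labels.
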