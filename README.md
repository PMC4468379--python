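# rrtzf — plant arginine-rich tandem zinc-finger (RR-TZF) family analysis

Plant RR-TZF proteins pair an arginine-rich region containing a **CHCH
motif** with a **tandem CCCH zinc-finger** domain, and act in abscisic-acid
signalling, salt/drought stress responses and the control of seed
germination. Family surveys define the domains by residue spacings —
`C-X7-8-C-X5-C-X3-H` for the first CCCH finger (generalised to
`C-X5-20-C-X5-C-X3-H`), `C-X5-C-X4-C-X3-H` for the second — and the whole
subfamily shares a diagnostic signature

```
K-X3-C-X5-H-X4-C-X3-H-X6-R-R-X6-Y-X4-C-X7-8-C-X5-C-X3-H-X2-F-E-X3-H-P-X7-C-X5-C-X4-C-F-F-A-H
```

`rrtzf` implements that analysis as a reusable, fully testable pipeline
for sequence curators and stress-biology groups:

* **motif_grammar** — a spacing-grammar engine: patterns are anchors with
  bounded wildcard spacers; `scan` enumerates every anchor placement.
* **architecture** — per-protein CHCH/CCCH1/CCCH2 calls, the tandem-linker
  check, ANK-repeat counting (group-I diagnostic), the IIa-diagnostic
  extra Cys at −12 from the first CHCH Cys, and the full-signature scan.
* **classify** — groups I–V and subgroups IIa (AtTZF1-2-3-like) / IIb
  (AtTZF4-5-like) by structural exclusion rules followed by
  nearest-labelled-exemplar percent identity with a 23% floor.
* **consensus** — per-column conservation profiles and consensus-signature
  derivation with `X7-8`-style spacer ranges.
* **align_phylo** — pairwise/progressive alignment, p-distances,
  neighbor-joining with explicit tie-breaks, column-bootstrap supports,
  Newick I/O.
* **expression** — 2^−ΔΔCT relative quantification (technical replicates
  averaged first, reference-gene and calibrator normalisation), log2 and
  angular (arcsine-square-root) transforms, one-way ANOVA with
  Bonferroni or Dunnett post hoc tests.
* **synth** — synthetic proteomes, CT tables and germination counts with
  planted ground truth, so every stage has a known answer.
* **seqprops** — ORF finding on intronless genes, molecular weight, pI.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each is a thin driver over the library; outputs land in
`results/`):

```sh
python analysis/01_simulate_data.py --seed 1
python analysis/02_scan_architecture.py
python analysis/03_classify_groups.py
```

which prints:

```
35 proteins scanned: 25 RR-TZF members, 5 near-miss proteins collected separately
membership agreement with planted truth: 100.0%
...
25 members classified (similarity floor 23%)
group recovery: 100.0%   subgroup recovery: 100.0%
group  subgroup
I      none         5
II     IIa         10
       IIb          5
V      none         5
```

Every planted class (IIa, IIa with the extra Cys, IIb, ANK-bearing group
I, long-spacer group V) is recovered exactly and all broken-spacing
decoys are rejected. Continuing with `04_consensus_signature.py`,
`05_phylogeny.py` and `06_expression_stats.py` derives a consensus
signature that re-matches 10/10 of its source sequences, validates
neighbor joining on 50 random additive matrices (max path-distance error
~1e-15), and recovers the planted salt-stress log2 fold changes, e.g.:

```
relative expression (log2, mean ± SE) vs planted design:
   NaCl_1h: +0.97 ± 0.02   (planted +1.0)
   NaCl_3h: +1.61 ± 0.02   (planted +1.7)
   NaCl_6h: +0.75 ± 0.04   (planted +0.8)
      mock: +0.00 ± 0.05   (planted +0.0)
```

A `tzf` command-line interface mirrors the stages
(`tzf scan | architecture | classify | consensus | tree | express | germ |
simulate | run`); `tzf run --seed 3 --out-dir out/` executes the pipeline
end to end.

Grammar-level scans are also directly available:

```pycon
>>> from rrtzf import load_grammars, scan, SequenceRecord
>>> g = load_grammars()
>>> scan(SequenceRecord("q", "IDAYSCDHFRMYDFKVRRCARGRSHDWTECPYAH"), g["CHCH"])
[MotifMatch(pattern_name='CHCH', start=19, end=34,
            anchors=(('C', 19), ('H', 25), ('C', 30), ('H', 34)))]
```

## Limitations

The bundled reference exemplars are synthetic stand-ins (see
`src/rrtzf/data/README.md`); for real surveys supply curated Arabidopsis
references via `--refs`. The progressive aligner is deterministic
pipeline plumbing, not a replacement for a production MSA tool. See
`docs/methods.md` for the model, parameter defaults and design choices.
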