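# Methods

## The spacing-grammar model

RR-TZF domain definitions are residue spacings, not profiles: a pattern
is an ordered list of anchors (exact residues or bracketed alternatives)
separated by bounded wildcard spacers, written `C-X(7,8)-C-X5-C-X3-H`.
The scanner enumerates *every* anchor placement (`mode=all`) because a
variable spacer can satisfy a pattern in several ways and the downstream
caller — not the engine — must own the selection policy. A
leftmost-greedy non-overlapping mode is provided for counting-style uses.
Anchors require the literal residue; the ambiguity code `X` in a subject
sequence is matched by spacers only, since anchors model the chemically
functional Cys/His of the zinc finger. Matching is case-insensitive;
gapped input is rejected rather than silently degapped.

Bundled grammars: `CCCH1_canonical` `C-X(7,8)-C-X5-C-X3-H`,
`CCCH1_general` `C-X(5,20)-C-X5-C-X3-H` (the enlarged first spacer covers
the monocot long-spacer forms up to 20 residues), `CCCH2`
`C-X5-C-X4-C-X3-H` plus the two rare variants `C-X4-…` and `C-X7-…`, the
CHCH motif `C-X5-H-X4-C-X3-H`, and the full family signature. The CHCH
spacing is not published as a standalone motif; it is read off the
signature and is therefore a configurable default rather than a fixed
constant. The hypothesised atypical overlapping domain
`C-X12-C-X10-C-X3-H` is reported as an annotation flag only and never
used for membership.

## Architecture calls

Components are selected N→C with a leftmost policy: the leftmost CHCH,
then the leftmost first CCCH starting after it, then the leftmost second
CCCH (canonical preferred over variants at equal position). Membership
(`is_rr_tzf`) requires all three simultaneously; near-miss proteins are
collected in a separate "excluded" report. The tandem linker between the
first domain's closing His and the second domain's opening Cys defaults
to an accepted range of 10–25 residues — 16 is the value fixed by the
signature, and the range acknowledges that "tandem" is used without
printed bounds. The first-CCCH spacer is binned into classes
(7–8 canonical, 9, 5, 10–20 long, other); the long class is supporting
evidence for group V. The IIa-diagnostic extra cysteine is checked at
offset −12 from the first CHCH Cys; the alternative reading (nine
residues upstream of the invariant Lys, i.e. −13) is selectable via
`extra_cys_offset` — the two published descriptions disagree by one
residue and the package does not adjudicate. ANK repeats come from an
external annotation table when provided; otherwise a documented 33-residue
synthetic ankyrin consensus is slid along the sequence and windows with
≥50% identity are counted non-overlapping. This is a pragmatic stand-in,
not a profile-HMM.

## Classification

Group and subgroup calls follow a structure-then-homology procedure.
Structure first: ANK repeats force group I and exclude a protein from the
subgroup comparison, as do non-canonical first-spacer classes and variant
second domains. Homology second: the nearest labelled exemplar by
pairwise global-alignment percent identity (BLOSUM62, gap open 10,
extend 0.5), with a minimum-similarity floor of 23%; below the floor the
protein stays unassigned. "Similarity" is implemented as percent
identity because identity is scoring-matrix-independent and reproducible;
a positives-based metric is available (`metric='positives'`). Identity
uses the multi-alignment convention throughout: identical pairs over
columns where at least one of the two rows has a residue. Ties on the
best exemplar break to the lexicographically smallest id, logged. The
pairwise route was chosen over re-deriving similarities from one large
MSA because it is deterministic and independent of the reference-set
composition; `similarity_matrix` is still provided for users who have an
MSA. The bundled exemplars are synthetic (planted-architecture)
stand-ins so classification runs without downloads; they are
user-replaceable, and the group IV/V taxonomic descriptions are evidence
annotations — no taxonomy database is consulted.

## Consensus signatures

A conservation profile records, per alignment column, the modal residue
(ties break to the lexicographically smallest), the identity fraction
among occupied rows and the occupancy fraction. "Invariant" defaults to
100% identity with ≥90% occupancy; the threshold is a knob because the
underlying notion has no published cutoff. Signature rendering measures
spacer lengths per row on the *ungapped* sequences between flanking
invariant columns, then prints `Xn` or a range `Xm-n`; this is what turns
a mixture of 7- and 8-residue spacers into `X7-8`. Leading/trailing
non-conserved runs are dropped so a signature always starts and ends on
an anchor, keeping it parseable by the grammar engine.

## Phylogeny

Neighbor joining is implemented directly so its determinism is explicit:
ties in the Saitou–Nei Q criterion break to the smallest (i, j) index
pair in the current node order; negative branch-length estimates are
clamped to zero with a warning. Distances default to p-distance
(1 − identity/100) on the supplied MSA — the original tool chain's
distance model is not recorded, and p-distance is the reproducible
choice; the distance function is a parameter. On additive matrices the
implementation recovers the generating topology and path distances to
machine precision (property-tested against randomly generated additive
trees, n ≤ 8, and cross-checked against scikit-bio's NJ). Bootstrap
supports resample alignment columns with replacement; an edge's support
is the percentage of replicate trees containing its bipartition, and the
default report hides values below 50%. The progressive aligner (NJ guide
tree, sum-of-pairs profile merges, linear gaps) exists so the pipeline
runs end to end without an external aligner; it is deterministic
plumbing, not a production MSA tool.

## Expression and germination statistics

2^−ΔΔCT quantification averages technical replicates first, forms
ΔCT = CT(target) − CT(reference) per (group, biological replicate),
subtracts the calibrator-group mean ΔCT, and exponentiates with
amplification efficiency fixed at 2 (no efficiency-corrected variant).
`log2_ratio = −ΔΔCT` exactly; standard errors are computed on log2 ratios
across biological replicates. Group testing runs one-way ANOVA on log2
ratios; Bonferroni post hoc tests are pairwise t tests on the pooled MSE
with p multiplied by the contrast count (capped at 1), and Dunnett
many-to-one tests use the equicorrelated multivariate-t distribution
(scipy's implementation; its randomised quadrature is seeded for
reproducibility). Germination proportions are variance-stabilised with
the angular transform arcsin(√p) before the same ANOVA machinery.
Single-replicate groups are refused with a clear error.

## Synthetic data and what it does (not) show

The generator plants exact grammar instances into random background:
classes IIa (first spacer 7), IIa-with-extra-Cys, IIb (spacer 8), group I
(three ankyrin-consensus copies), group V (spacer 10–20), decoys with
exactly one spacer pushed out of bounds, and fully random decoys.
Backgrounds are uniform over the 20 residues with Cys/His down-weighted
×0.3 so spurious hits stay rare (the spurious full-signature rate on
random decoys is measured and asserted < 1%); spacer fillers and point
mutations avoid C/H/K so they can erode homology without creating new
motif instances. Each planted protein is re-scanned after construction
and resampled (bounded retries) if a background collision perturbs the
planted truth — this guards collisions only; the truth coordinates are
fixed by construction. Class members are 25%-mutated copies of one class
prototype, so nearest-exemplar homology has a planted answer. CT tables
plant log2 fold changes as CT shifts with Gaussian noise (default
sd 0.15 cycles, 3 biological × 3 technical replicates, matching common
qPCR practice); germination tables draw binomial counts (default 75
seeds, 3 replicates, within the usual 50–100-seed range). All randomness
flows from one explicit seed.

What passing tests show: the scanning, classification, consensus, tree
and statistics machinery is correct on data whose truth is known. What
they do not show: recovery rates on real proteomes, where domain
boundaries blur, paralogs share partial architectures and alignments
carry indels — synthetic backgrounds have no phylogenetic covariance and
clade sequences are simple point-mutation radiations.

## Numerical choices and problem sizes

ΔΔCT recovery is assessed as *bias* — the mean recovery error across 40
replicate simulations per planted value — because a single n = 3 draw
measures sampling noise (≈0.1 log2 units), not estimator bias. Dunnett
calibration uses 1,000 null simulations (4 groups × 5 values). The
signature-consistency sweep uses 10,000 synthetic proteins (planted
classes plus random decoys so signature hits actually occur);
neighbor-joining validation uses 200 random additive matrices with 4–8
taxa; bootstrap checks use 8 taxa × 100 replicates. pI is found by
bisection of the Henderson–Hasselbalch net charge on pH [0, 14] to 1e-4,
with the EMBOSS pKa table named in the output — pI values are only
comparable within one pKa set, so cross-tool agreement is approximate by
nature. Molecular weights use average (not monoisotopic) residue masses.
ORF finding is forward-strand by default (the genes characterised this
way are intronless, genomic = cDNA); a six-frame flag exists for general
use, and ties on length break to the smallest start.
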