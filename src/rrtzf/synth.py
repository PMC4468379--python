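"""Synthetic data with planted ground truth for every pipeline stage.

Three generators give the scanning, classification, phylogeny and
expression stages a known answer:

* :func:`generate_proteome` — proteins with exact grammar instances of
  each architecture class embedded in random background, plus decoys with
  one spacer pushed out of bounds and fully random decoys;
* :func:`generate_ct_table` — long-format qPCR CT observations with
  planted log2 fold changes, a reference gene and Gaussian CT noise;
* :func:`generate_germination` — binomial germination counts at planted
  rates.

Background composition is uniform over the 20 residues with Cys and His
down-weighted (×0.3) so that spurious grammar hits stay rare; every
planted protein is re-scanned after construction and the background is
resampled (bounded retries) if a collision perturbs the planted truth.
Class members are point-mutated copies of a class prototype; mutations
never touch planted anchors and never introduce C, H or K, so they can
erode homology without creating new motif instances.  All randomness
flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import ANK_CONSENSUS_33
from .classify import ReferenceSet
from .io import SequenceRecord
from .motif_grammar import MotifPattern, load_grammars, scan

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: mutation / spacer-filler alphabet: no C (anchor everywhere), no H
#: (anchor), no K (signature start)
FILLER = "ADEFGILMNPQRSTVWY".replace("K", "")

CLASS_NAMES = ("IIa", "IIa_extra_cys", "IIb", "groupI_ank",
               "groupV_longspacer", "decoy_broken_spacing", "decoy_random")

EXTRA_CYS_OFFSET = -12


def background_frequencies(ch_weight: float = 0.3) -> np.ndarray:
    w = np.ones(len(AMINO_ACIDS))
    for i, a in enumerate(AMINO_ACIDS):
        if a in "CH":
            w[i] = ch_weight
    return w / w.sum()


@dataclass(frozen=True)
class ProteomeSpec:
    """Counts per class plus background/length parameters; seed mandatory."""

    counts: dict
    seed: int
    length_range: tuple[int, int] = (150, 250)
    ch_weight: float = 0.3
    mutation_rate: float = 0.25

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown class names {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class TruthLabel:
    protein_id: str
    class_name: str
    is_rr_tzf: bool
    group: str                  # I..V or 'none'
    subgroup: str               # IIa / IIb / 'none'
    coords: dict = field(default_factory=dict)  # planted 1-based anchor coords


@dataclass(frozen=True)
class ProteomeResult:
    records: tuple[SequenceRecord, ...]
    truth: tuple[TruthLabel, ...]
    references: ReferenceSet


# ---------------------------------------------------------------------------
# core construction
# ---------------------------------------------------------------------------

def _fill(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(FILLER), size=n)) if n else ""


def _background(rng: np.random.Generator, n: int, freqs: np.ndarray) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n, p=freqs)) if n else ""


def _core(rng: np.random.Generator, spacer1: int, ccch2_spacer1: int = 5) -> tuple[str, dict]:
    """Signature-scaffold core with explicit spacers.

    Returns the core string and 0-based offsets (relative to the core) of
    the planted components.  ``spacer1`` is the first CCCH domain's first
    spacer; ``ccch2_spacer1`` perturbs the second domain for decoys.
    """
    f = lambda n: _fill(rng, n)
    chunks: list[str] = []
    cursor = 0
    marks: dict[str, int] = {}

    def emit(s: str, mark: str | None = None) -> None:
        nonlocal cursor
        if mark is not None:
            marks[mark] = cursor
        chunks.append(s)
        cursor += len(s)

    emit("K", "signature")
    emit(f(3))
    emit("C", "chch")
    emit(f(5)); emit("H"); emit(f(4)); emit("C"); emit(f(3)); emit("H")
    emit(f(6)); emit("RR"); emit(f(6)); emit("Y"); emit(f(4))
    emit("C", "ccch1")
    emit(f(spacer1)); emit("C"); emit(f(5)); emit("C"); emit(f(3)); emit("H")
    emit(f(2)); emit("FE"); emit(f(3)); emit("HP"); emit(f(7))
    # signature tail C-X5-C-X4-C-F-F-A-H: "FFA" doubles as the second
    # domain's final X3 spacer
    emit("C", "ccch2")
    emit(f(ccch2_spacer1)); emit("C"); emit(f(4)); emit("C"); emit("FFAH")
    coords = dict(marks)
    coords["spacer1"] = spacer1
    return "".join(chunks), coords


def _leftmost_start(seq: str, pattern: MotifPattern) -> int | None:
    hits = scan(seq, pattern, mode="all")
    return hits[0].start if hits else None


def _verify_planted(seq: str, coords: dict, grammars: dict,
                    want_signature: bool, want_extra_cys: bool,
                    extra_cys_pos: int | None) -> bool:
    """Check the planted components are the leftmost grammar hits."""
    chch = _leftmost_start(seq, grammars["CHCH"])
    if chch != coords["chch"]:
        return False
    after_chch = coords["chch"] + 15  # CHCH end (C-X5-H-X4-C-X3-H spans 16)
    ccch1_hits = [m for m in scan(seq, grammars["CCCH1_general"], mode="all")
                  if m.start > after_chch]
    if not ccch1_hits or ccch1_hits[0].start != coords["ccch1"]:
        return False
    if ccch1_hits[0].anchors[1][1] - ccch1_hits[0].anchors[0][1] - 1 != coords["spacer1"]:
        return False
    after_ccch1 = ccch1_hits[0].end
    ccch2_hits = [m for m in scan(seq, grammars["CCCH2"], mode="all")
                  if m.start > after_ccch1]
    for var in ("CCCH2_variant_a", "CCCH2_variant_b"):
        var_hits = [m for m in scan(seq, grammars[var], mode="all")
                    if m.start > after_ccch1 and
                    (not ccch2_hits or m.start < ccch2_hits[0].start)]
        if var_hits:
            return False  # a variant would shadow the planted canonical domain
    if not ccch2_hits or ccch2_hits[0].start != coords["ccch2"]:
        return False
    has_sig = _leftmost_start(seq, grammars["SIGNATURE"]) is not None
    if has_sig != want_signature:
        return False
    if extra_cys_pos is not None and extra_cys_pos >= 1:
        is_c = seq[extra_cys_pos - 1] == "C"
        if is_c != want_extra_cys:
            return False
    return True


def _verify_decoy(seq: str, grammars: dict) -> bool:
    """True when the CHCH → CCCH1 → CCCH2 chain cannot be completed."""
    chch = _leftmost_start(seq, grammars["CHCH"])
    if chch is None:
        return True
    chch_end = [m for m in scan(seq, grammars["CHCH"], mode="all")][0].end
    ccch1 = [m for m in scan(seq, grammars["CCCH1_general"], mode="all")
             if m.start > chch_end]
    if not ccch1:
        return True
    for gname in ("CCCH2", "CCCH2_variant_a", "CCCH2_variant_b"):
        if any(m.start > ccch1[0].end
               for m in scan(seq, grammars[gname], mode="all")):
            return False
    return True


class _Builder:
    def __init__(self, spec: ProteomeSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.freqs = background_frequencies(spec.ch_weight)
        self.grammars = load_grammars()

    def _embed(self, core: str, coords: dict, ank_copies: int = 0
               ) -> tuple[str, dict]:
        """Place a core (plus optional ANK block) into random background."""
        rng = self.rng
        lo, hi = self.spec.length_range
        prefix_len = int(rng.integers(20, 41))
        ank_block = ANK_CONSENSUS_33 * ank_copies
        body = core + (_fill(rng, 6) + ank_block if ank_copies else "")
        suffix_len = max(20, int(rng.integers(lo, hi + 1)) - len(body) - prefix_len)
        seq = (_background(rng, prefix_len, self.freqs) + body
               + _background(rng, suffix_len, self.freqs))
        shifted = {k: (v + prefix_len + 1 if k != "spacer1" else v)
                   for k, v in coords.items()}
        shifted["ank_count"] = ank_copies
        return seq, shifted

    def prototype(self, spacer1: int, ank_copies: int = 0,
                  extra_cys: bool = False, max_tries: int = 50
                  ) -> tuple[str, dict]:
        """Build and verify one planted protein sequence."""
        for _ in range(max_tries):
            core, coords = _core(self.rng, spacer1)
            seq, shifted = self._embed(core, coords, ank_copies)
            ec_pos = shifted["chch"] + EXTRA_CYS_OFFSET
            if extra_cys:
                if ec_pos < 1:
                    continue
                seq = seq[: ec_pos - 1] + "C" + seq[ec_pos:]
            want_sig = spacer1 in (7, 8)
            if not _verify_planted(seq, shifted, self.grammars, want_sig,
                                   extra_cys, ec_pos):
                continue
            if ank_copies and self._ank_count(seq) != ank_copies:
                continue
            shifted["extra_cys_pos"] = ec_pos if extra_cys else None
            return seq, shifted
        raise RuntimeError("could not place planted motifs without collision")

    def _ank_count(self, seq: str) -> int:
        from .architecture import detect_ank
        return detect_ank(SequenceRecord("tmp", seq), source="builtin_consensus")

    def mutant(self, proto: str, coords: dict, plant_extra_cys: bool = False,
               max_tries: int = 50) -> str:
        """Point-mutated copy of a prototype, planted positions untouched.

        ``plant_extra_cys=True`` additionally writes a Cys at the −12
        offset from the first CHCH Cys (the IIa-diagnostic site).
        """
        protected = self._protected_positions(proto, coords)
        ec_pos = coords["chch"] + EXTRA_CYS_OFFSET
        for _ in range(max_tries):
            chars = list(proto)
            for i in range(len(chars)):
                if i in protected:
                    continue
                if self.rng.random() < self.spec.mutation_rate:
                    chars[i] = FILLER[int(self.rng.integers(len(FILLER)))]
            if plant_extra_cys:
                chars[ec_pos - 1] = "C"
            seq = "".join(chars)
            want_sig = coords["spacer1"] in (7, 8)
            extra = plant_extra_cys or coords.get("extra_cys_pos") is not None
            if _verify_planted(seq, coords, self.grammars, want_sig, extra, ec_pos):
                if coords.get("ank_count") and self._ank_count(seq) != coords["ank_count"]:
                    continue
                return seq
        raise RuntimeError("could not mutate prototype without breaking truth")

    def _protected_positions(self, proto: str, coords: dict) -> set[int]:
        """0-based positions of planted anchors (and the extra-Cys site)."""
        protected: set[int] = set()
        for gname in ("CHCH", "CCCH1_general", "CCCH2", "SIGNATURE"):
            for m in scan(proto, self.grammars[gname], mode="all"):
                protected.update(pos - 1 for _, pos in m.anchors)
        ec = coords.get("extra_cys_pos")
        if ec:
            protected.add(ec - 1)
        if coords.get("ank_count"):
            # protect the ANK block wholesale is unnecessary (50% identity
            # floor); protect nothing extra
            pass
        return protected

    def decoy_broken(self, kind: int) -> str:
        """Exactly one spacer pushed out of bounds; everything else intact."""
        for _ in range(50):
            if kind % 3 == 0:
                core, _ = _core(self.rng, spacer1=3)      # CCCH1 spacer < 5
            elif kind % 3 == 1:
                core, _ = _core(self.rng, spacer1=21)     # CCCH1 spacer > 20
            else:
                core, _ = _core(self.rng, spacer1=7, ccch2_spacer1=8)  # CCCH2 broken
            seq, _ = self._embed(core, {"spacer1": 0})
            if _verify_decoy(seq, self.grammars):
                return seq
        raise RuntimeError("could not build broken-spacing decoy")

    def decoy_random(self) -> str:
        lo, hi = self.spec.length_range
        n = int(self.rng.integers(lo, hi + 1))
        return _background(self.rng, n, self.freqs)


_CLASS_PLAN = {
    # class -> (prototype key, plant extra Cys, group, subgroup)
    "IIa": ("IIa", False, "II", "IIa"),
    "IIa_extra_cys": ("IIa", True, "II", "IIa"),
    "IIb": ("IIb", False, "II", "IIb"),
    "groupI_ank": ("I", False, "I", "none"),
    "groupV_longspacer": ("V", False, "V", "none"),
}

_PROTOTYPE_PLAN = {
    # key -> (spacer1, ank_copies, extra_cys, group label, sublabel)
    "I": (7, 3, False, "I", None),
    "IIa": (7, 0, False, "II", "IIa"),
    "IIb": (8, 0, False, "II", "IIb"),
    "III": (8, 0, False, "III", None),
    "IV": (7, 0, False, "IV", None),
    "V": (15, 0, False, "V", None),
}


def build_prototypes(builder: _Builder) -> dict[str, tuple[str, dict]]:
    return {
        key: builder.prototype(spacer1, ank, extra)
        for key, (spacer1, ank, extra, _, _) in _PROTOTYPE_PLAN.items()
    }


def make_reference_set(prototypes: dict[str, tuple[str, dict]],
                       provenance: str = "synthetic exemplars") -> ReferenceSet:
    exemplars = []
    labels: dict[str, str] = {}
    sublabels: dict[str, str] = {}
    for key, (spacer1, ank, extra, group, sub) in _PROTOTYPE_PLAN.items():
        if group is None:
            continue
        seq, _ = prototypes[key]
        rid = f"ref_{key}"
        exemplars.append(SequenceRecord(rid, seq, f"{rid} synthetic exemplar group={group}"
                                        + (f" subgroup={sub}" if sub else "")))
        labels[rid] = group
        if sub:
            sublabels[rid] = sub
    return ReferenceSet(tuple(exemplars), labels, sublabels, provenance)


def generate_proteome(spec: ProteomeSpec) -> ProteomeResult:
    """Planted-architecture proteome; deterministic given ``spec.seed``.

    Returns the records, per-protein truth labels, and the synthetic
    reference exemplars used to anchor classification.
    """
    rng = np.random.default_rng(spec.seed)
    builder = _Builder(spec, rng)
    prototypes = build_prototypes(builder)
    refs = make_reference_set(prototypes)

    records: list[SequenceRecord] = []
    truth: list[TruthLabel] = []
    for cls in CLASS_NAMES:
        n = spec.counts.get(cls, 0)
        for k in range(n):
            pid = f"{cls}_{k:03d}"
            if cls in _CLASS_PLAN:
                proto_key, extra, group, sub = _CLASS_PLAN[cls]
                proto_seq, coords = prototypes[proto_key]
                seq = builder.mutant(proto_seq, coords, plant_extra_cys=extra)
                ptruth = dict(coords)
                ptruth["extra_cys"] = extra
                truth.append(TruthLabel(pid, cls, True, group, sub, ptruth))
            elif cls == "decoy_broken_spacing":
                seq = builder.decoy_broken(k)
                truth.append(TruthLabel(pid, cls, False, "none", "none", {}))
            else:  # decoy_random
                seq = builder.decoy_random()
                truth.append(TruthLabel(pid, cls, False, "none", "none", {}))
            records.append(SequenceRecord(pid, seq, f"{pid} synthetic {cls}"))
    return ProteomeResult(tuple(records), tuple(truth), refs)


def random_additive_tree(n_taxa: int, rng: np.random.Generator,
                         min_branch: float = 0.1, max_branch: float = 1.0):
    """Random unrooted binary tree with positive branch lengths and its
    additive leaf-to-leaf distance matrix.

    Returns ``(DistanceMatrix, TreeNode)``.  Distances are exactly the
    tree's path lengths, so a correct neighbor-joining implementation must
    recover both the topology and the path distances.
    """
    from skbio import TreeNode

    from .align_phylo import DistanceMatrix, tree_path_distances

    if n_taxa < 4:
        raise ValueError("need at least 4 taxa for a non-trivial topology")
    nodes = [TreeNode(name=f"t{i:02d}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(min_branch, max_branch))
        b.length = float(rng.uniform(min_branch, max_branch))
        new = TreeNode(children=[b, a])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [new]
    for n in nodes:
        n.length = float(rng.uniform(min_branch, max_branch))
    tree = TreeNode(children=nodes)
    dm = tree_path_distances(tree)
    return DistanceMatrix(dm.ids, dm.values), tree


def generate_clade_alignment(leaves_per_clade: int = 2, length: int = 120,
                             seed: int | None = None,
                             deep_mut: float = 0.5, clade_mut: float = 0.2,
                             leaf_mut: float = 0.03):
    """Four well-separated clades by point-mutation radiation.

    A root protein radiates into two deep lineages, each into two clade
    ancestors, each into ``leaves_per_clade`` leaves; mutation pressure
    decreases towards the tips so clades are clearly separated.  No indels
    are introduced, so the sequences are returned as an alignment.
    Returns ``(Alignment, true_bipartitions)`` with bipartitions
    canonicalised as frozensets of leaf names (the side not containing the
    lexicographically smallest leaf).
    """
    from .io import Alignment

    rng = np.random.default_rng(seed)
    letters = list(AMINO_ACIDS)

    def mutate(seq: str, rate: float) -> str:
        chars = list(seq)
        for i in range(len(chars)):
            if rng.random() < rate:
                chars[i] = letters[int(rng.integers(len(letters)))]
        return "".join(chars)

    root = "".join(rng.choice(letters, size=length))
    lineages = [mutate(root, deep_mut) for _ in range(2)]
    records = []
    clade_names: list[list[str]] = []
    for li, lineage in enumerate(lineages):
        for ci in range(2):
            ancestor = mutate(lineage, clade_mut)
            names = []
            for k in range(leaves_per_clade):
                name = f"c{2 * li + ci}_{k}"
                names.append(name)
                records.append(SequenceRecord(name, mutate(ancestor, leaf_mut)))
            clade_names.append(names)
    all_names = sorted(r.id for r in records)
    ref = all_names[0]
    parts: set[frozenset[str]] = set()

    def canon(side: set[str]) -> frozenset[str]:
        if ref in side:
            side = set(all_names) - side
        return frozenset(side)

    for names in clade_names:
        if 2 <= len(names) <= len(all_names) - 2:
            parts.add(canon(set(names)))
    backbone = set(clade_names[0]) | set(clade_names[1])
    if 2 <= len(backbone) <= len(all_names) - 2:
        parts.add(canon(backbone))
    return Alignment(tuple(records)), parts


def reference_set_for_seed(seed: int) -> ReferenceSet:
    """Standalone synthetic reference exemplars for a given seed."""
    spec = ProteomeSpec(counts={}, seed=seed)
    builder = _Builder(spec, np.random.default_rng(seed))
    return make_reference_set(build_prototypes(builder))


# ---------------------------------------------------------------------------
# expression / germination
# ---------------------------------------------------------------------------

def generate_ct_table(groups: dict[str, float], target_gene: str = "target",
                      reference_gene: str = "ref", calibrator_group: str | None = None,
                      ct_base: float = 24.0, ref_base: float = 18.0,
                      noise_sd: float = 0.15, n_bio: int = 3, n_tech: int = 3,
                      seed: int | None = None) -> pd.DataFrame:
    """Long-format CT table with planted log2 fold changes per group.

    ``groups`` maps group label → planted log2 fold change relative to the
    calibrator (whose planted value should be 0).  Target CT is
    ``ct_base − fc + N(0, sd)`` per technical measurement; the reference
    gene sits at ``ref_base`` with the same noise.
    """
    if calibrator_group is None:
        calibrator_group = next(iter(groups))
    if calibrator_group not in groups:
        raise ValueError("calibrator group must be present in the design")
    rng = np.random.default_rng(seed)
    rows = []
    for group, fc in groups.items():
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                rows.append((target_gene, group, b, t,
                             ct_base - fc + rng.normal(0.0, noise_sd)))
                rows.append((reference_gene, group, b, t,
                             ref_base + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows, columns=["gene", "group", "bio_rep", "tech_rep", "ct"])


def generate_germination(rates: dict[tuple[str, str], float],
                         total_seeds: int = 75, n_rep: int = 3,
                         seed: int | None = None) -> pd.DataFrame:
    """Binomial germination counts at planted (genotype, condition) rates."""
    for key, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate for {key} outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for (genotype, condition), rate in rates.items():
        for rep in range(1, n_rep + 1):
            rows.append((genotype, condition, rep,
                         int(rng.binomial(total_seeds, rate)), total_seeds))
    return pd.DataFrame(rows, columns=["genotype", "condition", "replicate",
                                       "germinated", "total"])
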