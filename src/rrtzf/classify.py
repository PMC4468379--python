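"""Group and subgroup classification of RR-TZF proteins.

The family divides into five groups: group I carries ankyrin repeats;
group II (AtTZF1-5-like) splits into subgroup IIa (AtTZF1-2-3-like) and
IIb (AtTZF4-5-like); group III is AtTZF6-like; group IV is restricted to
gymnosperms and Solanum; group V (monocots and algae) shows the enlarged
first-CCCH spacing.  Assignment follows a structure-then-homology
procedure: structural exclusion rules first (ANK repeats, non-canonical
CCCH spacings), then nearest labelled exemplar by pairwise global
alignment identity, with a 23% minimum similarity floor.

"Similarity" is implemented as percent identity: identity is reproducible
whereas positives-based similarity depends on the scoring matrix; a
positives-based alternative can be selected via ``metric='positives'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align_phylo import global_align, similarity_matrix  # noqa: F401  (re-export)
from .architecture import ArchitectureReport
from .io import SequenceRecord
from .motif_grammar import parse_pattern, scan

log = logging.getLogger(__name__)

GROUPS = ("I", "II", "III", "IV", "V")
SUBGROUPS = ("IIa", "IIb")
DEFAULT_MIN_SIMILARITY = 23.0

#: Conserved motifs diagnostic within/around the RR-TZF region.  Positions
#: in the source alignments are not enforced; motifs are scanned anywhere.
DIAGNOSTIC_MOTIFS: dict[str, str] = {
    "LX[R/Q]YLP": "L-X-[R/Q]-Y-L-P",
    "[L/I]EEXPPMERVESGR": "[L/I]-E-E-X-P-P-M-E-R-V-E-S-G-R",
    "VXIPP": "V-X-I-P-P",
    "SPPSESPPLSP": "S-P-P-S-E-S-P-P-L-S-P",
    "NDVVASL": "N-D-V-V-A-S-L",
    "DVGWVSDLL": "D-V-G-W-V-S-D-L-L",
    "RYLP": "R-Y-L-P",        # IIa-diagnostic
    "RKLL": "R-K-L-L",        # IIb-diagnostic
    "CCLFC": "C-C-L-F-C",     # IIb-diagnostic
}


@dataclass(frozen=True)
class ReferenceSet:
    """Labelled exemplar sequences anchoring the group/subgroup space."""

    exemplars: tuple[SequenceRecord, ...]
    labels: dict[str, str]      # exemplar id -> group label I..V
    sublabels: dict[str, str]   # exemplar id -> IIa / IIb (group II only)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.exemplars:
            raise ValueError("empty reference set")
        ids = [e.id for e in self.exemplars]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate exemplar ids")
        for eid in self.labels:
            if eid not in ids:
                raise ValueError(f"label for unknown exemplar {eid!r}")
        for eid, sub in self.sublabels.items():
            if self.labels.get(eid) != "II":
                raise ValueError(f"sublabel {sub!r} on non-group-II exemplar {eid!r}")

    def group_ii(self) -> list[SequenceRecord]:
        return [e for e in self.exemplars if self.labels.get(e.id) == "II"]


@dataclass(frozen=True)
class GroupAssignment:
    protein_id: str
    group: str                  # I..V or 'unassigned'
    subgroup: str               # IIa / IIb / 'none'
    best_ref_id: str | None
    best_similarity: float      # percent
    basis: str                  # 'structure_rule' or 'nearest_reference'
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.subgroup != "none" and self.group != "II":
            raise ValueError("subgroup implies group II")
        if not (0.0 <= self.best_similarity <= 100.0):
            raise ValueError("similarity outside [0, 100]")


def load_reference_fasta(path) -> ReferenceSet:
    """Reference FASTA whose headers carry ``group=G`` (and optionally
    ``subgroup=S``) tags."""
    from .io import read_fasta
    exemplars = tuple(read_fasta(path))
    labels: dict[str, str] = {}
    sublabels: dict[str, str] = {}
    for e in exemplars:
        tags = dict(t.split("=", 1) for t in e.description.split() if "=" in t)
        if "group" not in tags:
            raise ValueError(f"exemplar {e.id}: header lacks a group=… tag")
        labels[e.id] = tags["group"]
        if "subgroup" in tags:
            sublabels[e.id] = tags["subgroup"]
    return ReferenceSet(exemplars, labels, sublabels, provenance=str(path))


def bundled_reference_set() -> ReferenceSet:
    """The package's synthetic exemplar set (see data/README.md)."""
    from importlib.resources import files
    return load_reference_fasta(files("rrtzf.data") / "synthetic_exemplars.fasta")


def _identity(a: SequenceRecord, b: SequenceRecord, metric: str = "identity") -> float:
    (ga, gb), _, ident = global_align(a, b)
    if metric == "identity":
        return ident
    if metric == "positives":
        from Bio.Align import substitution_matrices
        sub = substitution_matrices.load("BLOSUM62")
        pos = sum(1 for x, y in zip(ga, gb)
                  if x != "-" and y != "-" and sub[x, y] > 0)
        cols = sum(x != "-" or y != "-" for x, y in zip(ga, gb))
        return 100.0 * pos / cols if cols else 0.0
    raise ValueError(f"unknown similarity metric {metric!r}")


def _nearest(protein: SequenceRecord, exemplars: list[SequenceRecord],
             metric: str = "identity") -> tuple[str, float]:
    """Best exemplar by percent identity; ties broken by smallest id."""
    best_id, best_sim = None, -1.0
    for ex in sorted(exemplars, key=lambda e: e.id):
        sim = _identity(protein, ex, metric)
        if sim > best_sim + 1e-9:
            best_id, best_sim = ex.id, sim
        elif abs(sim - best_sim) <= 1e-9:
            log.info("similarity tie between %s and %s for %s; keeping %s",
                     best_id, ex.id, protein.id, best_id)
    return best_id, best_sim


def assign_subgroup(report: ArchitectureReport, protein: SequenceRecord,
                    refs: ReferenceSet,
                    min_similarity: float = DEFAULT_MIN_SIMILARITY,
                    metric: str = "identity") -> GroupAssignment:
    """Subgroup IIa/IIb call by structural exclusion then nearest exemplar.

    Step 1 excludes proteins structurally unlike the AtTZF1-5 set: any ANK
    repeats, a non-canonical first-CCCH spacing (only 7-8 passes), or a
    variant second CCCH domain.  Step 2 takes the most similar group-II
    exemplar; below ``min_similarity`` percent the protein stays
    unassigned.
    """
    if not report.is_rr_tzf:
        raise ValueError(f"{protein.id}: subgroup assignment requires an RR-TZF call")
    if (report.ank_count > 0 or report.spacer_class != "canonical_7_8"
            or report.ccch2_variant != "canonical"):
        return GroupAssignment(protein.id, "unassigned", "none", None, 0.0,
                               "structure_rule",
                               evidence=f"spacer_class={report.spacer_class},"
                                        f"ank={report.ank_count},"
                                        f"ccch2={report.ccch2_variant}")
    g2 = refs.group_ii()
    if not g2:
        raise ValueError("reference set has no group-II exemplars")
    best_id, best_sim = _nearest(protein, g2, metric)
    if best_sim < min_similarity:
        return GroupAssignment(protein.id, "unassigned", "none", best_id,
                               best_sim, "nearest_reference",
                               evidence="below similarity floor")
    return GroupAssignment(protein.id, "II", refs.sublabels[best_id],
                           best_id, best_sim, "nearest_reference")


def assign_group(report: ArchitectureReport, protein: SequenceRecord,
                 refs: ReferenceSet, metric: str = "identity") -> GroupAssignment:
    """Group I-V call: ANK repeats force group I, otherwise nearest
    exemplar over all labels.

    An enlarged first-CCCH spacer (10-20 residues) is recorded as
    supporting evidence for group V but does not override homology.
    """
    if report.ank_count > 0:
        return GroupAssignment(protein.id, "I", "none", None, 0.0,
                               "structure_rule", evidence=f"ank_count={report.ank_count}")
    best_id, best_sim = _nearest(protein, list(refs.exemplars), metric)
    group = refs.labels[best_id]
    evidence = ""
    if report.spacer_class == "long_10_20":
        evidence = "long first-CCCH spacer supports group V"
    sub = "none"
    return GroupAssignment(protein.id, group, sub, best_id, best_sim,
                           "nearest_reference", evidence=evidence)


def scan_diagnostic_motifs(protein: SequenceRecord) -> list[str]:
    """Names of the diagnostic conserved motifs present anywhere in the
    protein (X is a 1-residue wildcard, brackets are alternatives)."""
    present = []
    for name, expr in DIAGNOSTIC_MOTIFS.items():
        pattern = parse_pattern(expr, name=name)
        if scan(protein, pattern, mode="all"):
            present.append(name)
    return present


def classify_batch(reports: dict[str, ArchitectureReport],
                   proteins: list[SequenceRecord], refs: ReferenceSet,
                   min_similarity: float = DEFAULT_MIN_SIMILARITY) -> list[GroupAssignment]:
    """Group + subgroup calls for every RR-TZF member, in input order.

    Each protein is handled independently, so the batch is idempotent and
    order-independent.
    """
    out: list[GroupAssignment] = []
    for p in proteins:
        rep = reports[p.id]
        if not rep.is_rr_tzf:
            continue
        g = assign_group(rep, p, refs)
        if g.group == "II":
            s = assign_subgroup(rep, p, refs, min_similarity)
            g = GroupAssignment(p.id, "II" if s.subgroup != "none" else g.group,
                                s.subgroup, s.best_ref_id or g.best_ref_id,
                                s.best_similarity or g.best_similarity,
                                s.basis, evidence=s.evidence)
        out.append(g)
    return out
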