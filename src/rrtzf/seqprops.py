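"""Sequence-level characterisation of intronless genes and their proteins.

Covers the bookkeeping typically reported when a cloned gene is first
described: longest open reading frame on the forward strand, translation
under the standard genetic code, protein length, average molecular weight
and isoelectric point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Data.IUPACData import protein_weights
from Bio.Seq import Seq

from .io import SequenceRecord

log = logging.getLogger(__name__)

WATER_DA = 18.0153  # average mass of one water, Da

#: EMBOSS pKa values (iep program defaults); the table in use is reported in
#: output metadata because pI is pKa-set dependent.
PKA_SET_NAME = "EMBOSS"
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_SIDECHAIN_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
PKA_SIDECHAIN_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


@dataclass(frozen=True)
class OrfCall:
    """An ATG→stop open reading frame, 1-based inclusive nt coordinates."""

    start: int
    end: int
    protein: SequenceRecord

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.length_nt % 3 != 0:
            raise ValueError("ORF length not divisible by 3")
        if len(self.protein) != self.length_nt // 3 - 1:
            raise ValueError("protein length inconsistent with ORF length")


def translate(dna_frame: str) -> str:
    """Translate an in-frame CDS; the trailing stop is stripped, an
    internal stop is an error."""
    if len(dna_frame) % 3 != 0:
        raise ValueError("frame length not divisible by 3")
    prot = str(Seq(dna_frame).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError("internal stop codon in frame")
    return prot


def _forward_orfs(seq: str) -> list[tuple[int, int]]:
    """All ATG→stop ORFs on the forward strand, 0-based [start, end)."""
    stops = {"TAA", "TAG", "TGA"}
    orfs: list[tuple[int, int]] = []
    for frame in range(3):
        starts: list[int] = []
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG":
                starts.append(i)
            elif codon in stops:
                for s in starts:
                    orfs.append((s, i + 3))
                starts = []
    return orfs


def find_longest_orf(dna: SequenceRecord, six_frame: bool = False) -> OrfCall | None:
    """Longest ATG-to-stop frame; ties broken by smallest start.

    Forward strand only by default (intronless genes cloned as genomic =
    cDNA); ``six_frame=True`` also searches the reverse complement and
    reports coordinates on the forward strand.  Returns ``None`` when no
    ORF exists.
    """
    if dna.alphabet != "dna":
        raise ValueError("find_longest_orf expects a DNA record")
    if len(dna) < 6:
        raise ValueError("sequence shorter than one codon pair")
    seq = dna.residues
    candidates = [(e - s, s, e, False) for s, e in _forward_orfs(seq)]
    if six_frame:
        rc = str(Seq(seq).reverse_complement())
        candidates += [(e - s, s, e, True) for s, e in _forward_orfs(rc)]
    if not candidates:
        return None
    length, s, e, revcomp = max(candidates, key=lambda c: (c[0], -c[1]))
    source = str(Seq(seq).reverse_complement()) if revcomp else seq
    prot = translate(source[s:e])
    if revcomp:
        start, end = len(seq) - e + 1, len(seq) - s
    else:
        start, end = s + 1, e
    protein = SequenceRecord(f"{dna.id}_orf", prot, f"{dna.id} ORF", "protein")
    return OrfCall(start, end, protein)


def molecular_weight(protein: str | SequenceRecord) -> float:
    """Average (not monoisotopic) molecular weight in kDa.

    Sum of residue masses plus one water; the kDa value is conventionally
    reported to 2 decimals.  Ambiguity code ``X`` has no defined mass and
    is an error.
    """
    residues = protein.residues if isinstance(protein, SequenceRecord) else protein
    if not residues:
        raise ValueError("empty protein")
    if "X" in residues or "-" in residues:
        raise ValueError("mass undefined for ambiguity code X or gaps")
    # Biopython's protein_weights are free amino-acid masses; chain mass is
    # sum of (aa - water) residue masses + one water.
    mass = sum(protein_weights[a] - WATER_DA for a in residues) + WATER_DA
    return mass / 1000.0


def net_charge(protein: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge of the chain at a given pH."""
    pos = [PKA_NTERM] + [PKA_SIDECHAIN_POSITIVE[a] for a in protein
                         if a in PKA_SIDECHAIN_POSITIVE]
    neg = [PKA_CTERM] + [PKA_SIDECHAIN_NEGATIVE[a] for a in protein
                         if a in PKA_SIDECHAIN_NEGATIVE]
    q = sum(1.0 / (1.0 + 10 ** (ph - pka)) for pka in pos)
    q -= sum(1.0 / (1.0 + 10 ** (pka - ph)) for pka in neg)
    return q


def isoelectric_point(protein: str | SequenceRecord, tol: float = 1e-4) -> dict:
    """pI by bisection of the net-charge function over pH [0, 14].

    Returns ``{"pi": float, "pka_set": str}`` — the pKa table is named in
    the output because published tables differ by a few tenths of a pH
    unit and pI values are only comparable within one table.
    """
    residues = protein.residues if isinstance(protein, SequenceRecord) else protein
    if not residues:
        raise ValueError("empty protein")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(residues, mid) > 0:
            lo = mid
        else:
            hi = mid
    return {"pi": (lo + hi) / 2.0, "pka_set": PKA_SET_NAME}
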