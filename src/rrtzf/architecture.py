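"""Per-protein domain-architecture calls for the RR-TZF subfamily.

A protein belongs to the arginine-rich tandem zinc-finger (RR-TZF)
subfamily when it simultaneously carries a CHCH motif in the RR region
and the two tandem CCCH zinc fingers downstream of it.  This module
composes grammar scans into one :class:`ArchitectureReport` per protein:
the CHCH call, both CCCH domains with the realised first-spacer length,
the tandem-linker check, ANK-repeat counting, the subgroup-diagnostic
extra cysteine, and the full family signature.

Component selection proceeds N→C with a leftmost policy: the leftmost
CHCH, then the leftmost first CCCH starting after it, then the leftmost
second CCCH (canonical or variant) after that — mirroring the N-terminal
RR region preceding the tandem zinc-finger domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SequenceRecord
from .motif_grammar import MotifMatch, MotifPattern, load_grammars, scan

log = logging.getLogger(__name__)

DEFAULT_LINKER_RANGE = (10, 25)  # tandem linker; 16 in the family signature
DEFAULT_EXTRA_CYS_OFFSET = -12   # from the first CHCH Cys

#: A documented 33-residue ankyrin-repeat consensus used when no external
#: domain annotation is supplied.  It is a pragmatic, synthetic consensus in
#: the style of published ANK profiles, not a profile-HMM.
ANK_CONSENSUS_33 = "DGNTPLHLAARNGHLEVVKLLLEAGADVNARDK"

SPACER_CLASSES = ("canonical_7_8", "nine", "five", "long_10_20", "other")


@dataclass(frozen=True)
class ArchitectureReport:
    protein_id: str
    chch: MotifMatch | None
    ccch1: MotifMatch | None
    spacer1_length: int | None
    ccch2: MotifMatch | None
    ccch2_variant: str | None       # 'canonical', 'variant_a', 'variant_b'
    tandem_ok: bool
    ank_count: int
    extra_cys: bool
    signature_hit: MotifMatch | None
    atypical_overlap: bool = False  # hypothesised C-X12-C-X10-C-X3-H annotation

    @property
    def is_rr_tzf(self) -> bool:
        return self.chch is not None and self.ccch1 is not None and self.ccch2 is not None

    @property
    def spacer_class(self) -> str:
        s = self.spacer1_length
        if s is None:
            return "other"
        if s in (7, 8):
            return "canonical_7_8"
        if s == 9:
            return "nine"
        if s == 5:
            return "five"
        if 10 <= s <= 20:
            return "long_10_20"
        return "other"


def _leftmost(matches: list[MotifMatch], after: int = 0) -> MotifMatch | None:
    for m in matches:
        if m.start > after:
            return m
    return None


def check_extra_cys(protein: SequenceRecord, chch: MotifMatch,
                    offset: int = DEFAULT_EXTRA_CYS_OFFSET) -> bool:
    """Is there a Cys at ``offset`` (default −12) from the first CHCH Cys?

    This additional cysteine upstream of the motif is the diagnostic most
    enriched in the IIa subgroup.  An out-of-range position is reported as
    False with a warning, never an exception.
    """
    pos = chch.anchors[0][1] + offset  # 1-based
    if pos < 1 or pos > len(protein):
        log.warning(
            "%s: extra-Cys position %d out of range, reporting False",
            protein.id, pos,
        )
        return False
    return protein.residues[pos - 1] == "C"


def detect_ank(protein: SequenceRecord, source: str = "builtin_consensus",
               annotation: pd.DataFrame | None = None,
               min_identity: float = 0.5) -> int:
    """Count ankyrin repeats.

    ``annotation_table`` mode counts rows labelled ANK for the protein in a
    (protein_id, domain, start, end) table; ``builtin_consensus`` slides the
    33-residue consensus and keeps leftmost-greedy non-overlapping windows
    with at least ``min_identity`` anchor identity.
    """
    if source == "annotation_table":
        if annotation is None:
            raise ValueError("annotation_table mode requires an annotation table")
        rows = annotation[
            (annotation["protein_id"] == protein.id)
            & (annotation["domain"].str.upper() == "ANK")
        ]
        return len(rows)
    if source != "builtin_consensus":
        raise ValueError(f"unknown ANK source {source!r}")
    w = len(ANK_CONSENSUS_33)
    seq = protein.residues
    if len(seq) < w:
        return 0
    arr = np.frombuffer(seq.encode(), dtype="S1")
    cons = np.frombuffer(ANK_CONSENSUS_33.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(arr, w)
    ident = (windows == cons).mean(axis=1)
    count = 0
    i = 0
    while i < len(ident):
        if ident[i] >= min_identity:
            count += 1
            i += w  # leftmost-greedy, non-overlapping
        else:
            i += 1
    return count


def signature_scan(protein: SequenceRecord,
                   grammars: dict[str, MotifPattern] | None = None) -> MotifMatch | None:
    """Leftmost full RR-TZF signature match, or None.

    The signature is strictly stronger than the component filter: any
    protein carrying it also satisfies the CHCH + tandem-CCCH membership
    test.
    """
    grammars = grammars or load_grammars()
    return _leftmost(scan(protein, grammars["SIGNATURE"], mode="all"))


def call_architecture(protein: SequenceRecord,
                      grammars: dict[str, MotifPattern] | None = None,
                      linker_range: tuple[int, int] = DEFAULT_LINKER_RANGE,
                      extra_cys_offset: int = DEFAULT_EXTRA_CYS_OFFSET,
                      ank_annotation: pd.DataFrame | None = None) -> ArchitectureReport:
    """Compose grammar scans into one architecture report.

    Absent components are recorded as None; membership (``is_rr_tzf``)
    requires the CHCH motif and both CCCH domains simultaneously.
    """
    grammars = grammars or load_grammars()
    chch = _leftmost(scan(protein, grammars["CHCH"], mode="all"))

    ccch1 = None
    spacer1 = None
    if chch is not None:
        ccch1 = _leftmost(scan(protein, grammars["CCCH1_general"], mode="all"),
                          after=chch.end)
        if ccch1 is not None:
            spacer1 = ccch1.anchors[1][1] - ccch1.anchors[0][1] - 1

    ccch2 = None
    variant = None
    if ccch1 is not None:
        candidates: list[tuple[MotifMatch, str]] = []
        for gname, tag in (("CCCH2", "canonical"),
                           ("CCCH2_variant_a", "variant_a"),
                           ("CCCH2_variant_b", "variant_b")):
            m = _leftmost(scan(protein, grammars[gname], mode="all"), after=ccch1.end)
            if m is not None:
                candidates.append((m, tag))
        if candidates:
            candidates.sort(key=lambda c: (c[0].start, c[0].end, c[1]))
            ccch2, variant = candidates[0]

    tandem_ok = False
    if ccch1 is not None and ccch2 is not None:
        linker = ccch2.start - ccch1.end - 1
        tandem_ok = linker_range[0] <= linker <= linker_range[1]

    extra = False
    if chch is not None:
        extra = check_extra_cys(protein, chch, offset=extra_cys_offset)

    ank_source = "annotation_table" if ank_annotation is not None else "builtin_consensus"
    ank = detect_ank(protein, source=ank_source, annotation=ank_annotation)

    atypical = bool(scan(protein, grammars["ATYPICAL_OVERLAP"], mode="all"))

    return ArchitectureReport(
        protein_id=protein.id,
        chch=chch,
        ccch1=ccch1,
        spacer1_length=spacer1,
        ccch2=ccch2,
        ccch2_variant=variant,
        tandem_ok=tandem_ok,
        ank_count=ank,
        extra_cys=extra,
        signature_hit=signature_scan(protein, grammars),
        atypical_overlap=atypical,
    )


def _match_str(m: MotifMatch | None) -> str:
    return f"{m.start}-{m.end}" if m is not None else "."


def architecture_table(reports: list[ArchitectureReport]) -> pd.DataFrame:
    """Flatten reports to a TSV-ready table, one row per protein."""
    rows = []
    for r in reports:
        rows.append({
            "protein_id": r.protein_id,
            "is_rr_tzf": r.is_rr_tzf,
            "chch": _match_str(r.chch),
            "ccch1": _match_str(r.ccch1),
            "spacer1_length": r.spacer1_length if r.spacer1_length is not None else ".",
            "spacer_class": r.spacer_class,
            "ccch2": _match_str(r.ccch2),
            "ccch2_variant": r.ccch2_variant or ".",
            "tandem_ok": r.tandem_ok,
            "ank_count": r.ank_count,
            "extra_cys": r.extra_cys,
            "signature": _match_str(r.signature_hit),
            "atypical_overlap": r.atypical_overlap,
        })
    return pd.DataFrame(rows)


def split_excluded(reports: list[ArchitectureReport]) -> tuple[list[ArchitectureReport],
                                                               list[ArchitectureReport]]:
    """Separate members from near-miss proteins.

    Near-misses (some but not all of CHCH/CCCH1/CCCH2 present) are
    collected separately, mirroring how candidate proteins lacking one
    requirement are reported apart from the family proper.
    """
    members = [r for r in reports if r.is_rr_tzf]
    excluded = [
        r for r in reports
        if not r.is_rr_tzf and (r.chch or r.ccch1 or r.ccch2)
    ]
    return members, excluded
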