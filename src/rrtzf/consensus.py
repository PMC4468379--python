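"""Per-column conservation profiling and consensus-signature derivation.

Given a multiple alignment, each column gets a modal residue, an identity
fraction (share of the modal residue among occupied rows) and an
occupancy fraction.  A consensus *signature* then renders the invariant
columns as anchor residues and runs of non-conserved columns as bounded
spacers (``Xn`` or ``Xm-n``).  Spacer lengths are measured per row on the
ungapped sequences, not as gapped column counts — that is what turns a
mixture of 7- and 8-residue spacers into the familiar ``X7-8`` notation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .io import Alignment


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation summary of an alignment."""

    modal: tuple[str, ...]          # modal residue, '-' for all-gap columns
    identity: tuple[float, ...]     # modal count / occupied rows
    occupancy: tuple[float, ...]    # occupied rows / rows

    def __len__(self) -> int:
        return len(self.modal)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "column": range(1, len(self) + 1),
            "modal_residue": self.modal,
            "identity": self.identity,
            "occupancy": self.occupancy,
        })


def conservation_profile(alignment: Alignment) -> ConservationProfile:
    """Column-wise modal residue, identity and occupancy fractions.

    Ties on the modal residue break to the lexicographically smallest
    residue; an all-gap column reports modal '-', identity and occupancy 0.
    The profile is invariant under row permutation.
    """
    nrows = len(alignment.records)
    if nrows == 0:
        raise ValueError("empty alignment")
    modal: list[str] = []
    identity: list[float] = []
    occupancy: list[float] = []
    for j in range(1, alignment.column_count + 1):
        col = alignment.column(j)
        residues = [c for c in col if c != "-"]
        if not residues:
            modal.append("-")
            identity.append(0.0)
            occupancy.append(0.0)
            continue
        counts = Counter(residues)
        top = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        modal.append(top[0])
        identity.append(top[1] / len(residues))
        occupancy.append(len(residues) / nrows)
    return ConservationProfile(tuple(modal), tuple(identity), tuple(occupancy))


def _conserved_columns(profile: ConservationProfile, threshold: float,
                       min_occupancy: float, region: tuple[int, int]) -> list[int]:
    start, end = region
    if start < 1 or end > len(profile) or start > end:
        raise ValueError(f"empty or out-of-range region {region}")
    return [
        j for j in range(start, end + 1)
        if profile.identity[j - 1] >= threshold
        and profile.occupancy[j - 1] >= min_occupancy
        and profile.modal[j - 1] != "-"
    ]


def consensus_signature(alignment: Alignment,
                        invariant_threshold: float = 1.0,
                        region: tuple[int, int] | None = None,
                        min_occupancy: float = 0.9) -> str:
    """Render conserved columns as a spacing-grammar signature string.

    Columns with identity ≥ ``invariant_threshold`` (and occupancy ≥
    ``min_occupancy``) emit their residue; each maximal run of
    non-conserved columns emits a spacer whose length is the per-row count
    of residues between the flanking conserved columns.  When rows
    disagree the spacer renders as a range, e.g. ``X7-8``.  Leading and
    trailing non-conserved runs are dropped so the signature starts and
    ends on an anchor.
    """
    profile = conservation_profile(alignment)
    if region is None:
        region = (1, alignment.column_count)
    anchors = _conserved_columns(profile, invariant_threshold, min_occupancy, region)
    if not anchors:
        return ""
    rows = [r.residues for r in alignment.records]

    def spacer_lengths(c1: int, c2: int) -> tuple[int, int]:
        """Ungapped residue counts strictly between columns c1 and c2."""
        counts = [sum(1 for c in row[c1 : c2 - 1] if c != "-") for row in rows]
        return min(counts), max(counts)

    parts: list[str] = [profile.modal[anchors[0] - 1]]
    for prev, cur in zip(anchors, anchors[1:]):
        lo, hi = spacer_lengths(prev, cur)
        if hi > 0:
            parts.append(f"X{lo}" if lo == hi else f"X{lo}-{hi}")
        parts.append(profile.modal[cur - 1])
    return "-".join(parts)
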