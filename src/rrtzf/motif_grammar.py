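"""Spacing-grammar engine for CCCH/CHCH-style motif definitions.

Plant tandem zinc-finger domains are conventionally written as anchor
residues separated by bounded wildcard spacers — e.g. the first CCCH
domain as ``C-X(7,8)-C-X5-C-X3-H`` (three cysteines and a histidine with
characteristic spacings).  This module parses that mini-language into
:class:`MotifPattern` objects and enumerates every placement of a pattern
on a protein sequence.

Mini-language
-------------
Elements are '-'-separated (the separator is optional and purely
cosmetic):

* anchors: a single residue letter (``C``) or a bracketed alternative
  set (``[RQ]`` or ``[R/Q]``);
* spacers: ``X`` (exactly one wildcard residue), ``Xn`` (exactly *n*),
  ``X(m,n)`` or ``Xm-n`` (between *m* and *n* inclusive).

A pattern must start and end with an anchor.  In the subject sequence the
ambiguity code ``X`` is matched by spacers but never by an anchor — an
anchor requires the literal, chemically functional residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Union

from .io import SequenceRecord


@dataclass(frozen=True)
class Anchor:
    residues: frozenset[str]

    def render(self) -> str:
        if len(self.residues) == 1:
            return next(iter(self.residues))
        return "[" + "".join(sorted(self.residues)) + "]"


@dataclass(frozen=True)
class Spacer:
    min: int
    max: int

    def render(self) -> str:
        if self.min == self.max:
            return f"X{self.min}" if self.min != 1 else "X"
        return f"X({self.min},{self.max})"


Element = Union[Anchor, Spacer]


@dataclass(frozen=True)
class MotifPattern:
    """A named spacing grammar: ordered anchors with bounded spacers."""

    name: str
    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError(f"pattern {self.name!r}: no elements")
        if not isinstance(self.elements[0], Anchor) or not isinstance(
            self.elements[-1], Anchor
        ):
            raise ValueError(
                f"pattern {self.name!r}: must start and end with an anchor"
            )
        for s in self.elements:
            if isinstance(s, Spacer) and not (0 <= s.min <= s.max):
                raise ValueError(f"pattern {self.name!r}: bad spacer bounds {s}")

    @property
    def anchors(self) -> list[Anchor]:
        return [e for e in self.elements if isinstance(e, Anchor)]

    def render(self) -> str:
        return "-".join(e.render() for e in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    """A located pattern hit; all coordinates 1-based inclusive."""

    pattern_name: str
    start: int
    end: int
    anchors: tuple[tuple[str, int], ...]  # (residue, position)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


_TOKEN = re.compile(
    r"""
    X\((\d+),(\d+)\)      # X(m,n)
    |X(\d+)-(\d+)         # Xm-n
    |X(\d+)               # Xn
    |X                    # X  (single wildcard)
    |\[([A-WYZ/]+)\]      # bracketed anchor set, '/' separators allowed
    |([A-WYZ])            # single-letter anchor (X excluded: X is a spacer)
    |-                    # cosmetic separator
    |\s+
    """,
    re.VERBOSE,
)


def parse_pattern(text: str, name: str = "pattern") -> MotifPattern:
    """Parse mini-language ``text`` into a :class:`MotifPattern`.

    >>> p = parse_pattern("C-X(7,8)-C-X5-C-X3-H", name="ccch1")
    >>> len(p.anchors)
    4
    """
    text = text.strip()
    if not text:
        raise ValueError("empty pattern text")
    elements: list[Element] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise ValueError(f"pattern {name!r}: cannot parse at {text[pos:]!r}")
        g = m.groups()
        if g[0] is not None:
            elements.append(Spacer(int(g[0]), int(g[1])))
        elif g[2] is not None:
            elements.append(Spacer(int(g[2]), int(g[3])))
        elif g[4] is not None:
            elements.append(Spacer(int(g[4]), int(g[4])))
        elif g[5] is not None:
            residues = frozenset(g[5].replace("/", ""))
            if not residues:
                raise ValueError(f"pattern {name!r}: empty anchor set")
            elements.append(Anchor(residues))
        elif g[6] is not None:
            elements.append(Anchor(frozenset(g[6])))
        elif m.group(0) == "X":
            elements.append(Spacer(1, 1))
        pos = m.end()
    # merge nothing; validate shape via MotifPattern invariants
    merged: list[Element] = []
    for e in elements:
        if merged and isinstance(e, Spacer) and isinstance(merged[-1], Spacer):
            prev = merged.pop()
            merged.append(Spacer(prev.min + e.min, prev.max + e.max))
        else:
            merged.append(e)
    return MotifPattern(name, tuple(merged))


def _normalise(seq: SequenceRecord | str) -> str:
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    residues = residues.upper()
    if "-" in residues:
        raise ValueError("gapped sequences cannot be scanned; degap first")
    return residues


def _placements(seq: str, elements: tuple[Element, ...], i: int,
                acc: list[tuple[str, int]]) -> Iterator[tuple[tuple[str, int], ...]]:
    """Yield all anchor placements of ``elements`` starting at 0-based ``i``."""
    if not elements:
        yield tuple(acc)
        return
    head, rest = elements[0], elements[1:]
    if isinstance(head, Anchor):
        if i < len(seq) and seq[i] in head.residues:
            acc.append((seq[i], i + 1))
            yield from _placements(seq, rest, i + 1, acc)
            acc.pop()
    else:
        for k in range(head.min, head.max + 1):
            if i + k > len(seq):
                break
            yield from _placements(seq, rest, i + k, acc)


def scan(seq: SequenceRecord | str, pattern: MotifPattern,
         mode: str = "all") -> list[MotifMatch]:
    """Enumerate matches of ``pattern`` on a protein sequence.

    ``mode='all'`` returns every distinct anchor placement, sorted by
    (start, end).  ``mode='nonoverlapping'`` keeps a leftmost-greedy
    non-overlapping subset: earliest start first and, among matches with
    equal start, the shortest span.
    """
    if mode not in {"all", "nonoverlapping"}:
        raise ValueError(f"unknown scan mode {mode!r}")
    residues = _normalise(seq)
    first = pattern.elements[0]
    assert isinstance(first, Anchor)
    matches: list[MotifMatch] = []
    for i, res in enumerate(residues):
        if res not in first.residues:
            continue
        for anchors in _placements(residues, pattern.elements, i, []):
            matches.append(
                MotifMatch(pattern.name, anchors[0][1], anchors[-1][1], anchors)
            )
    matches.sort(key=lambda m: (m.start, m.end, m.anchors))
    if mode == "all":
        return matches
    selected: list[MotifMatch] = []
    cursor = 0  # last occupied position
    for m in matches:
        if m.start > cursor:
            selected.append(m)
            cursor = m.end
    return selected


# ---------------------------------------------------------------------------
# Bundled RR-TZF grammars.
#
# The first CCCH domain is canonically C-X7-8-C-X5-C-X3-H; family surveys
# broadened the first spacer to 5-20 residues (maize ZmTZF13 carries 20).
# The second CCCH domain is C-X5-C-X4-C-X3-H with two rare variants.  The
# CHCH motif spacing C-X5-H-X4-C-X3-H is read off the family signature
# (not printed on its own anywhere) and is therefore a configurable
# default rather than a fixed constant.
# ---------------------------------------------------------------------------

RR_TZF_GRAMMARS: dict[str, str] = {
    "CCCH1_canonical": "C-X(7,8)-C-X5-C-X3-H",
    "CCCH1_general": "C-X(5,20)-C-X5-C-X3-H",
    "CCCH2": "C-X5-C-X4-C-X3-H",
    "CCCH2_variant_a": "C-X4-C-X4-C-X3-H",
    "CCCH2_variant_b": "C-X7-C-X4-C-X3-H",
    "CHCH": "C-X5-H-X4-C-X3-H",
    "SIGNATURE": (
        "K-X3-C-X5-H-X4-C-X3-H-X6-R-R-X6-Y-X4-C-X(7,8)-C-X5-C-X3-H"
        "-X2-F-E-X3-H-P-X7-C-X5-C-X4-C-F-F-A-H"
    ),
    # hypothesised atypical domain overlapping the CHCH motif; reported as
    # an optional annotation only, never used for family membership
    "ATYPICAL_OVERLAP": "C-X12-C-X10-C-X3-H",
}


def load_grammars(source: dict[str, str] | str | None = None) -> dict[str, MotifPattern]:
    """Compile the bundled grammars, or a user dict / grammar file.

    A grammar file holds one ``name<TAB or spaces>pattern`` pair per line;
    '#' starts a comment.
    """
    if source is None:
        raw = dict(RR_TZF_GRAMMARS)
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        raw = {}
        with open(source) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                name, expr = line.split(None, 1)
                raw[name] = expr
    return {name: parse_pattern(expr, name=name) for name, expr in raw.items()}
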