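"""Alignment utilities, distance matrices and neighbor-joining phylogenies.

Pairwise global alignment is delegated to Biopython's ``PairwiseAligner``
(affine gaps, BLOSUM62 by default).  The neighbor-joining agglomeration
itself is implemented here so that its tie-break rule is explicit and
deterministic: among equal values of the Saitou–Nei Q criterion, the
lexicographically smallest (i, j) index pair in the current node order is
joined.  Negative branch-length estimates — a known artefact of NJ on
non-additive matrices — are clamped to zero with a warning.

Trees are held as :class:`skbio.TreeNode` objects (unrooted = trifurcating
root) so Newick round-trips use a standard writer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import TreeNode

from .io import Alignment, SequenceRecord

log = logging.getLogger(__name__)


def similarity_matrix(alignment: Alignment) -> tuple[list[str], np.ndarray]:
    """Pairwise percent similarity from a multiple alignment.

    ``similarity(i, j) = 100 × identical residue pairs / columns where at
    least one of i, j has a residue`` — the convention used when reading
    similarities off the distance matrix of a multi-alignment.  Symmetric,
    diagonal 100.  An all-gap row is an error.
    """
    rows = [r.residues for r in alignment.records]
    ids = [r.id for r in alignment.records]
    if len(rows) < 2:
        raise ValueError("similarity matrix needs at least 2 rows")
    for i, row in enumerate(rows):
        if set(row) == {"-"}:
            raise ValueError(f"row {ids[i]!r} is all gaps")
    n = len(rows)
    arrs = [np.frombuffer(r.encode(), dtype="S1") for r in rows]
    gap = b"-"
    sim = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[i], arrs[j]
            occupied = (a != gap) | (b != gap)
            ident = (a == b) & (a != gap)
            denom = int(occupied.sum())
            sim[i, j] = sim[j, i] = 100.0 * int(ident.sum()) / denom if denom else 0.0
    return ids, sim


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal distance matrix with ordered taxon ids."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("id count does not match matrix dimensions")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")
        np.fill_diagonal(self.values, 0.0)


def make_aligner(substitution_matrix: str = "BLOSUM62",
                 gap_open: float = 10.0, gap_extend: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(a: SequenceRecord | str, b: SequenceRecord | str,
                 substitution_matrix: str = "BLOSUM62",
                 gap_open: float = 10.0, gap_extend: float = 0.5,
                 ) -> tuple[tuple[str, str], float, float]:
    """Optimal global alignment under affine gaps.

    Returns ``((gapped_a, gapped_b), score, percent_identity)`` where
    identity counts identical residue pairs over alignment columns holding
    at least one residue.  Empty-vs-non-empty input yields an all-gap
    alignment with identity 0.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if "-" in sa or "-" in sb:
        raise ValueError("inputs to global_align must be ungapped")
    if not sa or not sb:
        ga = sa or "-" * len(sb)
        gb = sb or "-" * len(sa)
        return (ga, gb), 0.0, 0.0
    aligner = make_aligner(substitution_matrix, gap_open, gap_extend)
    aln = aligner.align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    ident = sum(x == y and x != "-" for x, y in zip(ga, gb))
    cols = sum(x != "-" or y != "-" for x, y in zip(ga, gb))
    return (ga, gb), float(aln.score), 100.0 * ident / cols if cols else 0.0


def percent_identity(a: SequenceRecord | str, b: SequenceRecord | str, **kw) -> float:
    return global_align(a, b, **kw)[2]


def p_distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """p-distance ``d = 1 − identity/100`` over MSA rows.

    Identity uses the same denominator convention as
    :func:`rrtzf.classify.similarity_matrix`: columns where at least one
    of the two rows has a residue.
    """
    ids, sim = similarity_matrix(alignment)
    return DistanceMatrix(tuple(ids), 1.0 - sim / 100.0)


def pairwise_distance_matrix(seqs: list[SequenceRecord], **kw) -> DistanceMatrix:
    """Distance matrix from all-vs-all pairwise global alignment identity."""
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - percent_identity(seqs[i], seqs[j], **kw) / 100.0
    return DistanceMatrix(tuple(s.id for s in seqs), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; deterministic given input order.

    Requires ≥3 taxa.  The returned tree is unrooted (root of degree 3);
    internal nodes are binary.  On an additive matrix the tree's path
    distances reproduce the input exactly.
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in matrix.ids]
    d = matrix.values.astype(float).copy()

    def clamp(x: float, where: str) -> float:
        if x < 0:
            if x < -1e-9:
                log.warning("negative NJ branch length %.3g at %s clamped to 0", x, where)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        # Q(i,j) = (m-2) d(i,j) - r_i - r_j ; pick min, ties by smallest (i,j)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li, child_i.name or "internal")
        child_j.length = clamp(lj, child_j.name or "internal")
        new = TreeNode(children=[child_i, child_j])
        dn = np.array([(d[i, k] + d[j, k] - d[i, j]) / 2.0
                       for k in range(m) if k not in (i, j)])
        keep = [k for k in range(m) if k not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = dn
        d[:-1, -1] = dn
        nodes = [nodes[k] for k in keep] + [new]

    # closed-form three-point resolution
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp((dab + dac - dbc) / 2.0, a.name or "internal")
    b.length = clamp((dab + dbc - dac) / 2.0, b.name or "internal")
    c.length = clamp((dac + dbc - dab) / 2.0, c.name or "internal")
    root = TreeNode(children=[a, b, c])
    return root


def tree_path_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree."""
    tips = sorted(tree.tips(), key=lambda t: t.name)
    ids = tuple(t.name for t in tips)
    n = len(ids)
    vals = np.zeros((n, n))
    dm = tree.tip_tip_distances(endpoints=list(ids))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            vals[i, j] = dm[a, b]
    return DistanceMatrix(ids, vals)


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalised as the side *not*
    containing the lexicographically smallest leaf."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    all_leaves = frozenset(leaves)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if ref in side:
            side = all_leaves - side
        parts.add(side)
    return parts


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(alignment: Alignment, replicates: int = 1000,
                      seed: int | None = None,
                      distance=p_distance_matrix) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    Alignment columns are resampled with replacement; the support of an
    internal edge is the percentage of replicate trees containing the
    corresponding bipartition.  Supports are stored in each internal
    node's ``support`` attribute (and written as internal node labels in
    Newick).  ``replicates=0`` returns the tree without supports.
    """
    main = nj_tree(distance(alignment))
    if replicates <= 0:
        return main
    rng = np.random.default_rng(seed)
    ncol = alignment.column_count
    counts: dict[frozenset[str], int] = {p: 0 for p in bipartitions(main)}
    rows = [r.residues for r in alignment.records]
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = Alignment(tuple(
            SequenceRecord(r.id, "".join(rows[k][c] for c in cols) or "-",
                           r.description, r.alphabet)
            for k, r in enumerate(alignment.records)
        ))
        try:
            rep_tree = nj_tree(distance(resampled))
        except ValueError:
            continue  # degenerate resample (e.g. all-gap row)
        rep_parts = bipartitions(rep_tree)
        for p in counts:
            if p in rep_parts:
                counts[p] += 1
    for node in main.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        leaves = sorted(t.name for t in main.tips())
        if leaves[0] in side:
            side = frozenset(leaves) - side
        if side in counts:
            node.support = 100.0 * counts[side] / replicates
    return main


def _support_map(tree: TreeNode) -> dict[frozenset[str], float]:
    out = {}
    for node in tree.non_tips(include_self=False):
        sup = getattr(node, "support", None)
        if sup is not None:
            out[frozenset(t.name for t in node.tips())] = sup
    return out


def _copy_with_supports(tree: TreeNode) -> TreeNode:
    # TreeNode.copy drops ad-hoc attributes; restore supports by clade
    supports = _support_map(tree)
    out = tree.copy()
    for node in out.non_tips(include_self=False):
        key = frozenset(t.name for t in node.tips())
        if key in supports:
            node.support = supports[key]
    return out


def filter_supports(tree: TreeNode, min_support: float = 50.0) -> TreeNode:
    """Hide bootstrap values below ``min_support`` (edge kept, label dropped)."""
    out = _copy_with_supports(tree)
    for node in out.non_tips(include_self=False):
        if getattr(node, "support", None) is not None and node.support < min_support:
            node.support = None
    return out


def write_newick(tree: TreeNode, path) -> None:
    """Write Newick; bootstrap supports become internal node labels
    (scikit-bio serialises the ``support`` attribute natively)."""
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    """Read Newick, interpreting numeric internal labels as supports."""
    tree = TreeNode.read(str(path), format="newick")
    tree.assign_supports()
    return tree


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

def _profile_align(pa: list[str], pb: list[str], sub, gap: float = -4.0
                   ) -> tuple[list[str], list[str]]:
    """Needleman–Wunsch on two profiles with sum-of-pairs scoring and
    linear gaps; deterministic (tie preference: diagonal, up, left)."""
    la, lb = len(pa[0]), len(pb[0])

    def col_score(i: int, j: int) -> float:
        tot, cnt = 0.0, 0
        for ra in pa:
            x = ra[i]
            if x == "-":
                continue
            for rb in pb:
                y = rb[j]
                if y == "-":
                    continue
                tot += sub[x][y]
                cnt += 1
        return tot / cnt if cnt else 0.0

    score = np.zeros((la + 1, lb + 1))
    ptr = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[:, 0] = np.arange(la + 1) * gap
    score[0, :] = np.arange(lb + 1) * gap
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = score[i - 1, j - 1] + col_score(i - 1, j - 1)
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            best = max(diag, up, left)
            score[i, j] = best
            ptr[i, j] = 0 if best == diag else (1 if best == up else 2)
    # traceback
    ga: list[list[str]] = [[] for _ in pa]
    gb: list[list[str]] = [[] for _ in pb]
    i, j = la, lb
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0 and i > 0 and j > 0:
            for k, ra in enumerate(pa):
                ga[k].append(ra[i - 1])
            for k, rb in enumerate(pb):
                gb[k].append(rb[j - 1])
            i -= 1
            j -= 1
        elif p == 1 and i > 0 or j == 0:
            for k, ra in enumerate(pa):
                ga[k].append(ra[i - 1])
            for k in range(len(pb)):
                gb[k].append("-")
            i -= 1
        else:
            for k in range(len(pa)):
                ga[k].append("-")
            for k, rb in enumerate(pb):
                gb[k].append(rb[j - 1])
            j -= 1
    return (["".join(reversed(r)) for r in ga], ["".join(reversed(r)) for r in gb])


def progressive_msa(seqs: list[SequenceRecord],
                    substitution_matrix: str = "BLOSUM62") -> Alignment:
    """Guide-tree progressive alignment.

    The guide tree is the NJ tree on pairwise global-alignment distances;
    profiles are merged in its postorder.  Deterministic, sum-of-pairs
    profile scoring with linear gaps — adequate for pipeline plumbing, not
    a replacement for a production aligner.
    """
    if len(seqs) == 0:
        return Alignment(())
    if len(seqs) == 1:
        return Alignment((seqs[0],))
    sub_np = substitution_matrices.load(substitution_matrix)
    letters = sub_np.alphabet
    sub = {a: {b: float(sub_np[a, b]) for b in letters} for a in letters}
    by_id = {s.id: s for s in seqs}
    if len(seqs) == 2:
        (ga, gb), _, _ = global_align(seqs[0], seqs[1],
                                      substitution_matrix=substitution_matrix)
        return Alignment((
            SequenceRecord(seqs[0].id, ga, seqs[0].description, seqs[0].alphabet),
            SequenceRecord(seqs[1].id, gb, seqs[1].description, seqs[1].alphabet),
        ))
    guide = nj_tree(pairwise_distance_matrix(seqs,
                                             substitution_matrix=substitution_matrix))

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        """Return (ids, gapped rows) for the subtree."""
        if node.is_tip():
            return [node.name], [by_id[node.name].residues]
        parts = [merge(c) for c in node.children]
        ids, rows = parts[0]
        for nids, nrows in parts[1:]:
            rows, nrows = _profile_align(rows, nrows, sub)
            ids = ids + nids
            rows = rows + nrows
        return ids, rows

    ids, rows = merge(guide)
    order = {s.id: k for k, s in enumerate(seqs)}
    recs = sorted(
        (SequenceRecord(i, row, by_id[i].description, by_id[i].alphabet)
         for i, row in zip(ids, rows)),
        key=lambda r: order[r.id],
    )
    return Alignment(tuple(recs))
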