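import itertools

import numpy as np
import pytest

from rrtzf.align_phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    filter_supports,
    global_align,
    nj_tree,
    p_distance_matrix,
    progressive_msa,
    read_newick,
    tree_path_distances,
    write_newick,
)
from rrtzf.io import Alignment, SequenceRecord
from rrtzf.synth import generate_clade_alignment, random_additive_tree


class TestGlobalAlign:
    def test_identical(self):
        (ga, gb), score, ident = global_align("MKVLH", "MKVLH")
        assert ident == 100.0 and "-" not in ga + gb

    def test_score_equals_exhaustive_oracle(self):
        """Affine-gap optimum verified by brute force over all alignments
        of tiny sequences."""
        from Bio.Align import substitution_matrices
        sub = substitution_matrices.load("BLOSUM62")
        gap_open, gap_extend = 10.0, 0.5

        def all_alignments(a, b):
            # every monotone pairing as gapped strings
            if not a and not b:
                yield "", ""
                return
            if a:
                for ga, gb in all_alignments(a[1:], b):
                    yield a[0] + ga, "-" + gb
            if b:
                for ga, gb in all_alignments(a, b[1:]):
                    yield "-" + ga, b[0] + gb
            if a and b:
                for ga, gb in all_alignments(a[1:], b[1:]):
                    yield a[0] + ga, b[0] + gb

        def affine_score(ga, gb):
            s = 0.0
            for row in (ga, gb):
                in_gap = False
                for c in row:
                    if c == "-":
                        s -= gap_extend if in_gap else gap_open
                        in_gap = True
                    else:
                        in_gap = False
            for x, y in zip(ga, gb):
                if x != "-" and y != "-":
                    s += sub[x, y]
            return s

        for a, b in [("ACD", "AD"), ("MKV", "MK"), ("WR", "WKR"), ("ACDE", "CE")]:
            best = max(affine_score(ga, gb) for ga, gb in all_alignments(a, b)
                       if not any(x == "-" and y == "-" for x, y in zip(ga, gb)))
            (_, _), score, _ = global_align(a, b)
            assert score == pytest.approx(best), (a, b)

    def test_empty_vs_nonempty(self):
        (ga, gb), score, ident = global_align("", "MK")
        assert (ga, gb) == ("--", "MK") and ident == 0.0

    def test_gapped_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("M-K", "MK")


class TestDistances:
    def test_p_distance_from_msa(self):
        aln = Alignment((SequenceRecord("a", "AAAA"), SequenceRecord("b", "AAAT")))
        dm = p_distance_matrix(aln)
        assert dm.values[0, 1] == pytest.approx(0.25)

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_known_additive_four_taxa(self):
        """((A:1,B:2),(C:3,D:4)) with internal edge 1: topology and branch
        lengths recovered."""
        ids = ("A", "B", "C", "D")
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], float)
        tree = nj_tree(DistanceMatrix(ids, d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        pd_ = tree_path_distances(tree)
        assert np.allclose(pd_.values, d, atol=1e-12)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(("a", "b", "c"), d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"a": 0.0, "b": 2.0, "c": 3.0}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))

    def test_random_additive_matrices_recovered(self):
        """Generating topology and path distances recovered to 1e-9 on
        random additive matrices, n ≤ 8."""
        rng = np.random.default_rng(17)
        for _ in range(40):
            n = int(rng.integers(4, 9))
            dm, true_tree = random_additive_tree(n, rng)
            tree = nj_tree(dm)
            assert bipartitions(tree) == bipartitions(true_tree)
            err = np.abs(tree_path_distances(tree).values - dm.values).max()
            assert err < 1e-9

    def test_agrees_with_skbio_on_additive_input(self):
        """Independent cross-check against scikit-bio's NJ."""
        import skbio
        rng = np.random.default_rng(3)
        dm, _ = random_additive_tree(6, rng)
        ours = nj_tree(dm)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids=list(dm.ids)))
        assert bipartitions(ours) == bipartitions(theirs)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        dm, _ = random_additive_tree(6, rng)
        perm = rng.permutation(len(dm.ids))
        dm2 = DistanceMatrix(tuple(dm.ids[i] for i in perm),
                             dm.values[np.ix_(perm, perm)])
        assert bipartitions(nj_tree(dm)) == bipartitions(nj_tree(dm2))

    def test_ultrametric_tie_break_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        ids = ("a", "b", "c", "d")
        t1 = nj_tree(DistanceMatrix(ids, d))
        t2 = nj_tree(DistanceMatrix(ids, d))
        assert t1.compare_rfd(t2) == 0
        # smallest (i,j) pair joined first -> (a,b) form a cherry
        assert bipartitions(t1) == {frozenset({"c", "d"})}

    def test_negative_branch_clamped(self, caplog):
        d = np.array([
            [0.0, 5.0, 9.0, 9.0],
            [5.0, 0.0, 10.0, 10.0],
            [9.0, 10.0, 0.0, 0.1],
            [9.0, 10.0, 0.1, 0.0],
        ])
        with caplog.at_level("WARNING"):
            tree = nj_tree(DistanceMatrix(("a", "b", "c", "d"), d))
        assert all(n.length is None or n.length >= 0
                   for n in tree.traverse())


class TestBootstrap:
    def test_same_seed_identical_supports(self):
        aln, _ = generate_clade_alignment(seed=2)
        t1 = bootstrap_support(aln, replicates=30, seed=9)
        t2 = bootstrap_support(aln, replicates=30, seed=9)
        s1 = sorted(getattr(n, "support", -1) for n in t1.non_tips(include_self=False))
        s2 = sorted(getattr(n, "support", -1) for n in t2.non_tips(include_self=False))
        assert s1 == s2

    def test_four_clades_high_support(self):
        """Clearly separated clades: every true internal edge ≥ 95% at 100
        replicates."""
        aln, true_parts = generate_clade_alignment(seed=3)
        tree = bootstrap_support(aln, replicates=100, seed=5)
        found = {frozenset(p): None for p in bipartitions(tree)}
        assert true_parts <= set(found)
        for node in tree.non_tips(include_self=False):
            sup = getattr(node, "support", None)
            assert sup is not None and sup >= 95.0

    def test_zero_replicates_no_supports(self):
        aln, _ = generate_clade_alignment(seed=2)
        tree = bootstrap_support(aln, replicates=0, seed=1)
        assert all(getattr(n, "support", None) is None
                   for n in tree.non_tips(include_self=False))

    def test_filter_supports_hides_low_values(self):
        aln, _ = generate_clade_alignment(seed=2)
        tree = bootstrap_support(aln, replicates=20, seed=1)
        for n in tree.non_tips(include_self=False):
            n.support = 30.0
        filtered = filter_supports(tree, min_support=50.0)
        assert all(getattr(n, "support", None) is None
                   for n in filtered.non_tips(include_self=False))


class TestNewick:
    def test_round_trip_preserves_topology_lengths_supports(self, tmp_path):
        aln, _ = generate_clade_alignment(seed=4)
        tree = bootstrap_support(aln, replicates=20, seed=2)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert bipartitions(back) == bipartitions(tree)
        orig = {frozenset(t.name for t in n.tips()): getattr(n, "support", None)
                for n in tree.non_tips(include_self=False)}
        rt = {frozenset(t.name for t in n.tips()): getattr(n, "support", None)
              for n in back.non_tips(include_self=False)}
        assert rt == orig
        t_len = {t.name: t.length for t in tree.tips()}
        b_len = {t.name: round(t.length, 10) for t in back.tips()}
        for k in t_len:
            assert b_len[k] == pytest.approx(t_len[k], abs=1e-9)


class TestProgressiveMsa:
    def test_degapping_recovers_inputs(self):
        rng = np.random.default_rng(12)
        seqs = []
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40))
        for i in range(5):
            s = list(base)
            for p in rng.choice(40, size=4, replace=False):
                if rng.random() < 0.5:
                    s[p] = ""
                else:
                    s[p] = "AC"[int(rng.integers(2))]
            seqs.append(SequenceRecord(f"s{i}", "".join(s)))
        msa = progressive_msa(seqs)
        assert msa.column_count >= 36
        degapped = {r.id: r.residues for r in (msa.degapped())}
        assert degapped == {s.id: s.residues for s in seqs}

    def test_single_and_pair(self):
        one = progressive_msa([SequenceRecord("a", "MKV")])
        assert one.column_count == 3
        two = progressive_msa([SequenceRecord("a", "MKVH"), SequenceRecord("b", "MKH")])
        assert two.column_count == 4
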