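import numpy as np
import pandas as pd
import pytest

from rrtzf.architecture import (
    ANK_CONSENSUS_33,
    architecture_table,
    call_architecture,
    check_extra_cys,
    detect_ank,
    signature_scan,
    split_excluded,
)
from rrtzf.io import SequenceRecord
from rrtzf.motif_grammar import scan
from rrtzf.synth import _core

from .conftest import QUERY_PEPTIDE


def make_iia_perfect(seed=0, spacer1=7):
    """The RR-region query peptide extended with an exact downstream CCCH1
    (given first spacer), 16-residue linker and canonical CCCH2."""
    rng = np.random.default_rng(seed)
    f = lambda n: "".join(rng.choice(list("ADEFGILMNPQRSTVWY"), size=n))
    ccch1 = "C" + f(spacer1) + "C" + f(5) + "C" + f(3) + "H"
    linker = f(16)
    ccch2 = "C" + f(5) + "C" + f(4) + "C" + f(3) + "H"
    seq = QUERY_PEPTIDE + f(4) + ccch1 + linker + ccch2 + f(10)
    return SequenceRecord("iia_perfect", seq)


class TestCallArchitecture:
    def test_iia_perfect_is_member(self, grammars):
        rec = make_iia_perfect()
        rep = call_architecture(rec, grammars)
        assert rep.is_rr_tzf
        assert rep.chch.start == 19           # CHCH of the query region
        assert rep.spacer1_length == 7
        assert rep.spacer_class == "canonical_7_8"
        assert rep.ccch2_variant == "canonical"
        assert rep.tandem_ok

    def test_spacer_stretched_to_20_is_long_class(self, grammars):
        rep = call_architecture(make_iia_perfect(spacer1=20), grammars)
        assert rep.is_rr_tzf
        assert rep.spacer1_length == 20
        assert rep.spacer_class == "long_10_20"

    @pytest.mark.parametrize("spacer1,klass", [
        (7, "canonical_7_8"), (8, "canonical_7_8"), (9, "nine"),
        (5, "five"), (12, "long_10_20"),
    ])
    def test_spacer_classes(self, grammars, spacer1, klass):
        rep = call_architecture(make_iia_perfect(spacer1=spacer1), grammars)
        assert rep.spacer_class == klass

    def test_chch_deleted_not_member(self, grammars):
        rec = make_iia_perfect()
        # break the CHCH by mutating its first Cys (position 19)
        broken = rec.residues[:18] + "A" + rec.residues[19:]
        rep = call_architecture(SequenceRecord("x", broken), grammars)
        assert not rep.is_rr_tzf and rep.chch is None

    def test_missing_ccch2_goes_to_excluded(self, grammars):
        rec = make_iia_perfect()
        trunc = SequenceRecord("t", rec.residues[:60])  # CHCH + CCCH1 only
        reps = [call_architecture(trunc, grammars),
                call_architecture(make_iia_perfect(), grammars)]
        members, excluded = split_excluded(reps)
        assert [r.protein_id for r in members] == ["iia_perfect"]
        assert [r.protein_id for r in excluded] == ["t"]

    def test_determinism_and_order_independence(self, grammars, small_proteome):
        recs = list(small_proteome.records)
        fwd = [call_architecture(r, grammars) for r in recs]
        rev = [call_architecture(r, grammars) for r in reversed(recs)]
        assert fwd == list(reversed(rev))


class TestExtraCys:
    def test_planted_cys_detected(self, grammars):
        rec = make_iia_perfect()
        chch = call_architecture(rec, grammars).chch
        pos = chch.anchors[0][1] - 12
        planted = rec.residues[: pos - 1] + "C" + rec.residues[pos:]
        assert check_extra_cys(SequenceRecord("p", planted), chch)

    def test_absent_by_default(self, grammars):
        rec = make_iia_perfect()
        rep = call_architecture(rec, grammars)
        assert not rep.extra_cys

    def test_out_of_range_warns_false(self, grammars, caplog):
        seq = "C" + "A" * 5 + "H" + "A" * 4 + "C" + "A" * 3 + "H" + "A" * 20
        rec = SequenceRecord("edge", seq)
        chch = scan(rec, grammars["CHCH"])[0]
        with caplog.at_level("WARNING"):
            assert check_extra_cys(rec, chch) is False
        assert "out of range" in caplog.text

    def test_configurable_offset(self, grammars):
        """The alternative reading (−13, nine residues upstream of the
        invariant Lys) is selectable."""
        rec = make_iia_perfect()
        chch = call_architecture(rec, grammars).chch
        pos = chch.anchors[0][1] - 13
        planted = rec.residues[: pos - 1] + "C" + rec.residues[pos:]
        prec = SequenceRecord("p", planted)
        assert check_extra_cys(prec, chch, offset=-13)
        assert not check_extra_cys(prec, chch, offset=-12)


class TestAnk:
    def test_annotation_table_mode(self):
        ann = pd.DataFrame({
            "protein_id": ["p1", "p1", "p2"],
            "domain": ["ANK", "ANK", "TZF"],
            "start": [1, 40, 5], "end": [33, 72, 30],
        })
        rec = SequenceRecord("p1", "M" * 40)
        assert detect_ank(rec, source="annotation_table", annotation=ann) == 2

    def test_annotation_fixture_file(self, data_dir):
        ann = pd.read_csv(data_dir / "ank_annotation.tsv", sep="\t")
        assert detect_ank(SequenceRecord("p1", "M" * 40),
                          source="annotation_table", annotation=ann) == 2
        assert detect_ank(SequenceRecord("p2", "M" * 40),
                          source="annotation_table", annotation=ann) == 0

    def test_builtin_consensus_exact_copies(self):
        rec = SequenceRecord("a", ANK_CONSENSUS_33 * 3)
        assert detect_ank(rec, source="builtin_consensus") == 3

    def test_builtin_no_hit_on_random(self):
        rng = np.random.default_rng(1)
        rec = SequenceRecord("r", "".join(rng.choice(list("ADEFGILMNPQRSTVWY"), 200)))
        assert detect_ank(rec, source="builtin_consensus") == 0

    def test_unknown_source_is_error(self):
        with pytest.raises(ValueError, match="unknown"):
            detect_ank(SequenceRecord("x", "MKV"), source="nonsense")


class TestSignature:
    def test_signature_instance_hits_and_implies_membership(self, grammars):
        rng = np.random.default_rng(5)
        core, _ = _core(rng, spacer1=7)
        rec = SequenceRecord("sig", "GAVLIM" + core + "TSPNQD")
        m = signature_scan(rec, grammars)
        assert m is not None
        assert rec.residues[m.end - 5 : m.end] == "CFFAH"
        assert call_architecture(rec, grammars).is_rr_tzf

    def test_rr_mutated_kills_signature(self, grammars):
        rng = np.random.default_rng(5)
        core, _ = _core(rng, spacer1=7)
        rec = SequenceRecord("sig", core)
        m = signature_scan(rec, grammars)
        rr_pos = [p for r, p in m.anchors if r == "R"]
        broken = list(rec.residues)
        broken[rr_pos[1] - 1] = "A"
        assert signature_scan(SequenceRecord("b", "".join(broken)), grammars) is None

    def test_spacer9_fails_signature_but_passes_general_filter(self, grammars):
        rng = np.random.default_rng(5)
        core, _ = _core(rng, spacer1=9)
        rec = SequenceRecord("s9", core)
        assert signature_scan(rec, grammars) is None
        rep = call_architecture(rec, grammars)
        assert rep.is_rr_tzf and rep.spacer_class == "nine"


def test_architecture_table_columns(grammars, small_proteome):
    reports = [call_architecture(r, grammars) for r in small_proteome.records[:4]]
    df = architecture_table(reports)
    assert list(df.columns)[:3] == ["protein_id", "is_rr_tzf", "chch"]
    assert len(df) == 4
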