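import numpy as np
import pytest

from mybfam.classify import (
    ClassifyConfig,
    SubfamilyCall,
    assign_names,
    classify_protein,
    summarize_family,
)
from mybfam.seqio import ProteinRecord
from mybfam.synthetic_data import BACKBONE_ALPHABET

R2 = "W" + "A" * 19 + "W" + "A" * 19 + "W"
R3 = "F" + "A" * 18 + "W" + "A" * 18 + "W"
RR1 = "W" + "A" * 19 + "W" + "A" * 19 + "Y"


def _backbone(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(BACKBONE_ALPHABET), size=n))


class TestClassifyProtein:
    def test_two_tandem_repeats_is_r2r3(self):
        call = classify_protein(ProteinRecord("p", R2 + "G" * 5 + R3))
        assert call.subfamily == "R2R3"
        assert call.related_type is None
        assert len(call.evidence) == 2

    def test_three_tandem_repeats_is_3r(self):
        seq = R2 + "G" * 5 + R2 + "G" * 5 + R3
        assert classify_protein(ProteinRecord("p", seq)).subfamily == "R3_MYB"

    def test_four_tandem_repeats_is_4r(self):
        seq = R2 + "G" * 5 + R2 + "G" * 5 + R2 + "G" * 5 + R3
        assert classify_protein(ProteinRecord("p", seq)).subfamily == "R4_MYB"

    def test_distant_repeats_do_not_chain(self):
        # gap far beyond the tandem threshold: two R but not tandem
        seq = R2 + _backbone(80) + R3
        call = classify_protein(ProteinRecord("p", seq))
        assert call.subfamily == "MYB_RELATED"
        assert call.related_type == "UNCLASSIFIED"

    def test_single_shaqk_is_cca1_like(self):
        call = classify_protein(ProteinRecord("p", _backbone(30) + "SHAQKYF" + _backbone(30)))
        assert (call.subfamily, call.related_type) == ("MYB_RELATED", "CCA1_LIKE")

    def test_rr_repeat_far_before_shaqk_is_r_r(self):
        seq = RR1 + _backbone(60) + "SHAQKFF"
        call = classify_protein(ProteinRecord("p", seq))
        assert (call.subfamily, call.related_type) == ("MYB_RELATED", "R_R")

    def test_rr_repeat_too_close_to_shaqk_falls_back_to_cca1(self):
        # separation below the "far apart" threshold
        seq = RR1 + _backbone(20) + "SHAQKFF"
        call = classify_protein(ProteinRecord("p", seq))
        assert (call.subfamily, call.related_type) == ("MYB_RELATED", "CCA1_LIKE")

    def test_tbp_motif_is_tbp_like(self):
        call = classify_protein(ProteinRecord("p", _backbone(25) + "LKDKWRN" + _backbone(25)))
        assert (call.subfamily, call.related_type) == ("MYB_RELATED", "TBP_LIKE")

    def test_shlqk_with_lheqle_is_myb_cc(self):
        seq = _backbone(20) + "SHLQKAR" + _backbone(40) + "LHEQLE" + _backbone(20)
        call = classify_protein(ProteinRecord("p", seq))
        assert (call.subfamily, call.related_type) == ("MYB_RELATED", "MYB_CC")

    def test_shlqk_alone_is_garp_like(self):
        call = classify_protein(ProteinRecord("p", _backbone(20) + "SHLQMGR" + _backbone(20)))
        assert (call.subfamily, call.related_type) == ("MYB_RELATED", "GARP_LIKE")

    def test_no_evidence_is_not_myb(self):
        call = classify_protein(ProteinRecord("p", _backbone(100)))
        assert call.subfamily == "NOT_MYB"
        assert call.evidence == ()

    def test_tbp_beats_shlq_precedence(self):
        # documented precedence: TBP fires before GARP when both motifs occur
        seq = _backbone(10) + "SHLQKAR" + _backbone(10) + "LKDKWRN" + _backbone(10)
        call = classify_protein(ProteinRecord("p", seq))
        assert call.related_type == "TBP_LIKE"

    def test_pure_function_of_sequence(self):
        seq = ProteinRecord("p", R2 + "G" * 5 + R3)
        a = classify_protein(seq)
        b = classify_protein(seq)
        assert a == b

    def test_custom_tandem_gap_changes_chaining(self):
        seq = R2 + _backbone(25) + R3  # gap 25: start2 - end1 = 14
        default = classify_protein(ProteinRecord("p", seq))
        wide = classify_protein(
            ProteinRecord("p", seq), config=ClassifyConfig(tandem_gap=20)
        )
        assert default.subfamily == "MYB_RELATED"
        assert wide.subfamily == "R2R3"


class TestAssignNames:
    def test_counter_semantics(self):
        calls = [
            SubfamilyCall("a", "R2R3", evidence=(1,)),
            SubfamilyCall("b", "MYB_RELATED", related_type="CCA1_LIKE", evidence=(1,)),
            SubfamilyCall("c", "R2R3", evidence=(1,)),
        ]
        names = [c.assigned_name for c in assign_names(calls)]
        assert names == ["CwMYB1", "CwMYBR1", "CwMYB2"]

    def test_3r_and_4r_numbering(self):
        calls = [
            SubfamilyCall("a", "R3_MYB", evidence=(1,)),
            SubfamilyCall("b", "R3_MYB", evidence=(1,)),
            SubfamilyCall("c", "R4_MYB", evidence=(1,)),
        ]
        names = [c.assigned_name for c in assign_names(calls)]
        assert names == ["CwMYB3R1", "CwMYB3R2", "CwMYB4R1"]

    def test_not_myb_unnamed_and_empty_list(self):
        assert assign_names([]) == []
        calls = assign_names([SubfamilyCall("a", "NOT_MYB")])
        assert calls[0].assigned_name is None

    def test_permutation_changes_only_numbering(self):
        seqs = [
            ProteinRecord("a", R2 + "G" * 5 + R3),
            ProteinRecord("b", _backbone(20) + "SHAQKYF"),
            ProteinRecord("c", R2 + "G" * 5 + R2 + "G" * 5 + R3),
        ]
        fwd = {c.seq_id: c for c in assign_names([classify_protein(s) for s in seqs])}
        rev = {c.seq_id: c for c in assign_names([classify_protein(s) for s in reversed(seqs)])}
        for sid in fwd:
            assert fwd[sid].subfamily == rev[sid].subfamily
            assert fwd[sid].related_type == rev[sid].related_type


class TestSummarizeFamily:
    def test_counts(self):
        calls = [
            SubfamilyCall("a", "R2R3", evidence=(1,)),
            SubfamilyCall("b", "R2R3", evidence=(1,)),
            SubfamilyCall("c", "MYB_RELATED", related_type="CCA1_LIKE", evidence=(1,)),
        ]
        table = summarize_family(calls)
        assert table["count"].sum() == 3
        assert table.set_index(["subfamily", "related_type"]).loc[("R2R3", ""), "count"] == 2
        assert (
            table.set_index(["subfamily", "related_type"]).loc[("MYB_RELATED", "CCA1_LIKE"), "count"]
            == 1
        )

    def test_all_not_myb(self):
        calls = [SubfamilyCall(f"s{i}", "NOT_MYB") for i in range(3)]
        table = summarize_family(calls)
        assert table["count"].sum() == 3
        assert table.set_index("subfamily").loc["NOT_MYB", "count"] == 3


class TestSubfamilyCallInvariants:
    def test_related_type_requires_myb_related(self):
        with pytest.raises(ValueError):
            SubfamilyCall("a", "R2R3", related_type="CCA1_LIKE", evidence=(1,))
        with pytest.raises(ValueError):
            SubfamilyCall("a", "MYB_RELATED", evidence=(1,))

    def test_evidence_required_unless_not_myb(self):
        with pytest.raises(ValueError):
            SubfamilyCall("a", "R2R3")
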