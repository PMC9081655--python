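import numpy as np
import pytest

from conftest import (
    FULL_AA,
    hits_as_tuples,
    oracle_detect,
    oracle_ear,
    random_protein,
)
from mybfam.repeat_scan import (
    SIGNATURE_PATTERNS,
    MotifPattern,
    PatternError,
    ScanConfig,
    Spacer,
    compile_pattern,
    detect_repeats,
    find_motif,
    scan_ear,
)
from mybfam.seqio import ProteinRecord

R2_BLOCK = "W" + "A" * 19 + "W" + "A" * 19 + "W"
R3_BLOCK = "F" + "A" * 18 + "W" + "A" * 18 + "W"


class TestCompilePattern:
    def test_r2_consensus(self):
        p = compile_pattern("W-x(19)-W-x(19)-W")
        assert p.positions == (
            frozenset("W"),
            Spacer(19, 19),
            frozenset("W"),
            Spacer(19, 19),
            frozenset("W"),
        )

    def test_r3_consensus_residue_class(self):
        p = compile_pattern("[FILM]-x(18)-W-x(18)-W")
        assert p.positions[0] == frozenset("FILM")
        assert p.positions[1] == Spacer(18, 18)

    def test_variable_spacer(self):
        p = compile_pattern("W-x(18,19)-W")
        assert p.positions[1] == Spacer(18, 19)

    @pytest.mark.parametrize("bad", ["x(5)", "W-x(", "W-[Z]", "W--W", "W-x(3,2)-W"])
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(PatternError):
            compile_pattern(bad)


class TestFindMotif:
    def test_shaqk_exact_match(self):
        hits = find_motif(
            ProteinRecord("m", "AASHAQKYFAA"), SIGNATURE_PATTERNS["SHAQK"]
        )
        assert [(h.start, h.matched) for h in hits] == [(2, "SHAQKYF")]

    def test_tbp_spans_whole_sequence(self):
        hits = find_motif(ProteinRecord("m", "LKDKWRN"), SIGNATURE_PATTERNS["TBP"])
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (0, 7)

    def test_anchor_free_alphabet_yields_nothing(self, rng):
        seq = ProteinRecord("m", "".join(rng.choice(list("AGS"), size=200)))
        for name, pat in SIGNATURE_PATTERNS.items():
            assert find_motif(seq, pat) == [], name

    def test_x_never_matches_anchor_positions(self):
        # X in place of the [YF] position must not match
        assert find_motif(ProteinRecord("m", "SHAQKXF"), SIGNATURE_PATTERNS["SHAQK"]) == []

    def test_matched_equals_slice(self):
        seq = ProteinRecord("m", "LALALAL")
        for h in find_motif(seq, SIGNATURE_PATTERNS["EAR"]):
            assert h.matched == seq.sequence[h.start : h.end]


class TestDetectRepeats:
    def test_exact_r2_consensus(self):
        hits = detect_repeats(ProteinRecord("t", R2_BLOCK))
        assert hits_as_tuples(hits) == {(0, (0, 20, 40), "R2_CONSENSUS")}

    def test_exact_r3_consensus(self):
        hits = detect_repeats(ProteinRecord("t", R3_BLOCK))
        assert hits_as_tuples(hits) == {(0, (0, 19, 38), "R3_CONSENSUS")}

    def test_r2_then_r3_two_hits(self):
        seq = R2_BLOCK + "G" * 5 + R3_BLOCK
        hits = detect_repeats(ProteinRecord("t", seq))
        assert [(h.repeat_class, h.anchors) for h in hits] == [
            ("R2_CONSENSUS", (0, 20, 40)),
            ("R3_CONSENSUS", (46, 65, 84)),
        ]
        assert hits_as_tuples(hits) == oracle_detect(seq)

    def test_rr_first_tyrosine_anchor(self):
        seq = "W" + "A" * 19 + "W" + "A" * 19 + "Y"
        hits = detect_repeats(ProteinRecord("t", seq))
        assert hits_as_tuples(hits) == {(0, (0, 20, 40), "RR_FIRST")}

    def test_spacer_slack_accepts_off_by_one(self):
        seq = "W" + "A" * 18 + "W" + "A" * 20 + "W"
        hits = detect_repeats(ProteinRecord("t", seq))
        assert len(hits) == 1
        assert hits[0].repeat_class == "R2_CONSENSUS"

    def test_slack_zero_rejects_off_by_one(self):
        seq = "W" + "A" * 18 + "W" + "A" * 20 + "W"
        hits = detect_repeats(ProteinRecord("t", seq), ScanConfig(slack=0))
        assert hits == []

    def test_planted_r2_found_regardless_of_position(self, rng):
        from mybfam.synthetic_data import BACKBONE_ALPHABET

        for p in (0, 7, 50):
            backbone = "".join(rng.choice(list(BACKBONE_ALPHABET), size=120))
            seq = backbone[:p] + R2_BLOCK + backbone[p:]
            hits = detect_repeats(ProteinRecord("t", seq))
            assert hits_as_tuples(hits) == {(p, (p, p + 20, p + 40), "R2_CONSENSUS")}

    def test_append_after_last_hit_is_invariant(self):
        seq = R2_BLOCK + "G" * 20
        base = hits_as_tuples(detect_repeats(ProteinRecord("t", seq)))
        ext = hits_as_tuples(detect_repeats(ProteinRecord("t", seq + "AGSAGS")))
        assert base == ext

    def test_hits_sorted_and_cores_disjoint(self, rng):
        for _ in range(50):
            rec = random_protein(rng)
            hits = detect_repeats(rec)
            starts = [h.start for h in hits]
            assert starts == sorted(starts)
            for a, b in zip(hits, hits[1:]):
                assert b.start > a.anchors[2]

    def test_matches_bruteforce_oracle_on_random_sequences(self, rng):
        # dense-anchor alphabet exercises overlap resolution harder than
        # the uniform alphabet does
        alphabets = [list(FULL_AA), list("WYFAILM"), list("WA")]
        for i in range(60):
            alpha = alphabets[i % len(alphabets)]
            n = int(rng.integers(1, 120))
            seq = "".join(rng.choice(alpha, size=n))
            got = hits_as_tuples(detect_repeats(ProteinRecord("t", seq)))
            assert got == oracle_detect(seq), seq


class TestScanEar:
    def test_simple_match_outside_repeats(self):
        hits = scan_ear(ProteinRecord("t", "AALKLALAA"), [])
        assert [(h.start, h.matched) for h in hits] == [(2, "LKLAL")]

    def test_overlapping_matches_all_reported(self):
        hits = scan_ear(ProteinRecord("t", "LLLLLL"), [])
        assert [(h.start, h.end) for h in hits] == [(0, 5), (1, 6)]

    def test_match_inside_repeat_interval_suppressed(self):
        seq = R2_BLOCK[:5] + "LALAL" + R2_BLOCK[10:]
        rec = ProteinRecord("t", seq)
        # fake repeat covering the whole sequence
        from mybfam.repeat_scan import RepeatHit

        fake = RepeatHit("t", 0, len(seq), (0, 20, 40), "R2_CONSENSUS", ("W", "W", "W"))
        assert scan_ear(rec, [fake]) == []

    def test_agrees_with_exhaustive_window_oracle(self, rng):
        for _ in range(30):
            rec = random_protein(rng, max_len=150)
            repeats = detect_repeats(rec)
            got = {(h.start, h.end) for h in scan_ear(rec, repeats)}
            want = oracle_ear(rec.sequence, [(r.start, r.end) for r in repeats])
            assert got == want
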