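import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdtr.imgt import (AnchorError, ImgtPosition, assign_g_numbering,
                       assign_v_numbering, cdr3_positions, load_g_domain_references,
                       map_imgt_to_author, render_position_map)
from gdtr.synthetic import (chain_from_sequence, gen_domain_sequence,
                            rts88_like_v_gamma, sc19_like_v_delta)

P = ImgtPosition.parse


class TestImgtPositionOrder:
    def test_hand_enumerated_oracle(self):
        """CDR3 insertions ascend after 111 and descend into 112."""
        ordered = ["104", "105", "111", "111.1", "111.2", "112.2", "112.1",
                   "112", "117", "118"]
        shuffled = ["112.1", "104", "118", "111.2", "112", "111", "117",
                    "112.2", "105", "111.1"]
        assert [str(p) for p in sorted(P(t) for t in shuffled)] == ordered

    def test_letter_insertions_ascend(self):
        assert P("72") < P("72A") < P("72B") < P("73")

    @given(st.lists(st.sampled_from(
        ["104", "105", "111", "111.1", "111.5", "112.6", "112.1", "112",
         "72", "72A", "117", "118"]), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sorting_is_idempotent(self, labels):
        positions = [P(t) for t in labels]
        assert sorted(sorted(positions)) == sorted(positions)

    def test_single_insertion_kind(self):
        with pytest.raises(ValueError):
            ImgtPosition(111, numeric_insertion=1, letter_insertion="A")


class TestCdr3Positions:
    @pytest.mark.parametrize("length", range(1, 41))
    def test_occupied_count_equals_length(self, length):
        pos = cdr3_positions(length)
        assert len(pos) == length
        assert sorted(pos) == pos
        n_ins = sum(1 for p in pos if p.numeric_insertion is not None)
        assert n_ins == max(0, length - 13)

    def test_length_13_is_gapless(self):
        assert [str(p) for p in cdr3_positions(13)] == [str(b) for b in range(105, 118)]

    def test_length_15_inserts_111_1_and_112_1(self):
        labels = {str(p) for p in cdr3_positions(15)}
        assert {"111.1", "112.1"} <= labels
        assert "111.2" not in labels

    def test_odd_extra_favors_111_side(self):
        labels = {str(p) for p in cdr3_positions(16)}
        assert {"111.1", "111.2", "112.1"} <= labels

    def test_short_loop_gaps_at_apex(self):
        assert [str(p) for p in cdr3_positions(5)] == ["105", "106", "107", "116", "117"]


class TestAssignVNumbering:
    def test_rts88_like_lengths(self):
        n = assign_v_numbering(rts88_like_v_gamma())
        assert n.cdr_lengths == (6, 8, 15)

    def test_sc19_like_lengths_and_insertions(self):
        n = assign_v_numbering(sc19_like_v_delta())
        assert n.cdr_lengths == (7, 3, 37)
        occupied = {str(p) for p in n.positions()}
        assert {"111.7", "111.9", "111.10", "112.6"} <= occupied

    def test_anchor_residues(self):
        n = assign_v_numbering(sc19_like_v_delta())
        assert n.position_map[P("23")] == "C"
        assert n.position_map[P("41")] == "W"
        assert n.position_map[P("104")] == "C"
        assert n.position_map[P("118")] in "FW"

    def test_exact_13_cdr3_has_no_insertions(self):
        seq, truth = gen_domain_sequence(kind="V", cdr_lengths=(6, 8, 13), seed=4)
        n = assign_v_numbering(seq)
        assert n.cdr_lengths == (6, 8, 13)
        cdr3 = [str(p) for p in n.region_positions("CDR3")]
        assert cdr3 == [str(b) for b in range(105, 118)]

    @pytest.mark.parametrize("seed", range(12))
    def test_generated_domains_round_trip(self, seed):
        lengths = [(5, 6, 10), (6, 8, 15), (7, 3, 37), (4, 4, 20)][seed % 4]
        seq, truth = gen_domain_sequence(kind="V", cdr_lengths=lengths, seed=seed)
        n = assign_v_numbering(seq)
        assert n.cdr_lengths == lengths

    def test_flanking_context_with_hints_matches_bare_domain(self):
        bare = assign_v_numbering(rts88_like_v_gamma())
        flanked = "MKTAG" + rts88_like_v_gamma() + "AKTT"
        with_hints = assign_v_numbering(flanked, hints={"start": 5})
        assert with_hints.position_map == bare.position_map

    def test_anchorless_sequence_fails(self):
        with pytest.raises(AnchorError):
            assign_v_numbering("ACDEFGHIKLMNPQRSTVWY" * 5)


class TestAssignGNumbering:
    def test_reference_numbers_itself_identically(self):
        ref = load_g_domain_references()["G-ALPHA1-LIKE"]
        n = assign_g_numbering(ref.sequence, ref)
        assert [str(p) for p in n.positions()] == ref.positions
        assert n.sequence() == ref.sequence
        assert not n.unaligned

    def test_duplicated_residue_after_72_becomes_72A(self):
        ref = load_g_domain_references()["G-ALPHA2-LIKE"]
        idx = ref.positions.index("72")
        seq = ref.sequence[: idx + 1] + ref.sequence[idx] + ref.sequence[idx + 1:]
        n = assign_g_numbering(seq, ref)
        assert n.position_map[P("72A")] == ref.sequence[idx]

    def test_camdro_like_alpha2_carries_ser_72a(self):
        ref = load_g_domain_references()["G-ALPHA2-LIKE"]
        seq, _ = gen_domain_sequence(kind="G", g_reference=ref,
                                     g_insertion=("72", "S"), n_substitutions=8, seed=6)
        n = assign_g_numbering(seq, ref)
        assert n.position_map[P("72A")] == "S"

    def test_helix_annotation(self):
        ref = load_g_domain_references()["G-ALPHA1-LIKE"]
        n = assign_g_numbering(ref.sequence, ref)
        assert n.region_of[P("55")] == "helix"
        assert n.region_of[P("10")] == "strand"

    def test_non_g_domain_rejected(self):
        ref = load_g_domain_references()["G-ALPHA1-LIKE"]
        with pytest.raises(ValueError, match="not a G-domain"):
            assign_g_numbering("AAAA", ref)


class TestCorrespondence:
    def test_sc19_like_fig3_author_numbers(self):
        """A model chain numbered 1..n reproduces the printed IMGT->PDB
        correspondences for the long-CDR3 V-delta."""
        n = assign_v_numbering(sc19_like_v_delta())
        chain = chain_from_sequence(sc19_like_v_delta(), "D")
        corr = map_imgt_to_author(n, chain)
        assert corr.to_author("109") == (96, "")
        assert corr.to_author("111.4") == (102, "")
        assert corr.to_author("111.5") == (103, "")
        assert corr.to_author("111.7") == (105, "")

    def test_rts88_like_position_38_maps_to_author_32(self):
        n = assign_v_numbering(rts88_like_v_gamma())
        corr = map_imgt_to_author(n, chain_from_sequence(rts88_like_v_gamma(), "G"))
        assert corr.to_author("38") == (32, "")

    def test_roundtrip_is_identity(self):
        n = assign_v_numbering(rts88_like_v_gamma())
        chain = chain_from_sequence(rts88_like_v_gamma(), "G", start=7)
        corr = map_imgt_to_author(n, chain)
        for pos in n.positions():
            author, icode = corr.to_author(pos)
            assert str(corr.to_imgt(author, icode)) == str(pos)

    def test_missing_domain_reports_best_partial_match(self):
        n = assign_v_numbering(rts88_like_v_gamma())
        other = chain_from_sequence(sc19_like_v_delta(), "D")
        with pytest.raises(ValueError, match="best partial match"):
            map_imgt_to_author(n, other)


class TestRenderPositionMap:
    def test_cdr3_row_counts_match_loop_lengths(self):
        text_g = render_position_map(assign_v_numbering(rts88_like_v_gamma()))
        text_d = render_position_map(assign_v_numbering(sc19_like_v_delta()))
        assert sum(1 for line in text_g.splitlines() if line.endswith("\tCDR3")) == 15
        assert sum(1 for line in text_d.splitlines() if line.endswith("\tCDR3")) == 37

    def test_empty_numbering_renders_header_only(self):
        from gdtr.imgt import DomainNumbering
        empty = DomainNumbering("V-DOMAIN", {}, {})
        assert render_position_map(empty).strip() == "imgt\taa\tregion"
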