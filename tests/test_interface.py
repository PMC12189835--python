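import numpy as np
import pytest

from conftest import brute_force_interface
from gdtr.interface import (ContactParams, ContactTable, InteractionType,
                            classify_pair, contact_table, interface_residues,
                            summarize_table)
from gdtr.structures import Atom, ChainModel, ComplexStructure, Residue
from gdtr.synthetic import (DEFAULT_CONTACT_DISTANCES, gen_complex_fixture,
                            gen_interaction_fixture)

ALL_TYPES = list(InteractionType)

#: Upper threshold of each type's window (lower bound only for aromatic).
THRESHOLDS = {
    InteractionType.IONIC: 6.0,
    InteractionType.HBOND_SS: 3.5,
    InteractionType.HBOND_MS: 3.5,
    InteractionType.HBOND_MM: 3.5,
    InteractionType.AROMATIC_AROMATIC: 7.0,
    InteractionType.AROMATIC_SULFUR: 5.3,
    InteractionType.CATION_PI: 6.0,
    InteractionType.HYDROPHOBIC: 5.0,
}


def _planted_pair(s):
    return s.chain("A").residues[0], s.chain("B").residues[0]


def _kinds(res_a, res_b):
    return {c.kind for c in classify_pair(res_a, res_b)}


class TestClassifyPair:
    def test_arg_asp_at_5A_is_ionic(self):
        s, _ = gen_interaction_fixture(InteractionType.IONIC, distance=5.0, seed=1)
        assert InteractionType.IONIC in _kinds(*_planted_pair(s))

    def test_aromatic_window_boundaries(self):
        s, _ = gen_interaction_fixture(InteractionType.AROMATIC_AROMATIC, 6.0, seed=2)
        assert InteractionType.AROMATIC_AROMATIC in _kinds(*_planted_pair(s))
        s, _ = gen_interaction_fixture(InteractionType.AROMATIC_AROMATIC, 4.0, seed=2)
        assert InteractionType.AROMATIC_AROMATIC not in _kinds(*_planted_pair(s))

    @pytest.mark.parametrize("kind", ALL_TYPES)
    def test_threshold_sweep_flips_exactly_at_cutoff(self, kind):
        """Planted geometries on both sides of each threshold."""
        cut = THRESHOLDS[kind]
        for offset, expected in ((-0.2, True), (0.2, False)):
            s, _ = gen_interaction_fixture(kind, cut + offset, seed=7)
            present = kind in _kinds(*_planted_pair(s))
            assert present is expected, f"{kind} at {cut + offset}"

    @pytest.mark.parametrize("kind", ALL_TYPES)
    def test_classification_is_symmetric(self, kind):
        s, _ = gen_interaction_fixture(kind, seed=3)
        ra, rb = _planted_pair(s)
        ab = {(c.kind, c.distance) for c in classify_pair(ra, rb)}
        ba = {(c.kind, c.distance) for c in classify_pair(rb, ra)}
        assert ab == ba

    def test_defining_distance_matches_plant(self):
        for kind, d in DEFAULT_CONTACT_DISTANCES.items():
            s, _ = gen_interaction_fixture(kind, seed=4)
            contacts = [c for c in classify_pair(*_planted_pair(s)) if c.kind == kind]
            assert contacts and contacts[0].distance == pytest.approx(d, abs=2e-3)

    def test_missing_side_chain_skipped_with_warning(self):
        bare_arg = Residue("ARG", 1, atoms=[Atom("CA", "C", [0, 0, 0])])
        asp = Residue("ASP", 2, atoms=[Atom("OD1", "O", [3, 0, 0]),
                                       Atom("CA", "C", [5, 0, 0])])
        with pytest.warns(UserWarning, match="ionic skipped"):
            contacts = classify_pair(bare_arg, asp)
        assert InteractionType.IONIC not in {c.kind for c in contacts}

    def test_his_is_both_cationic_and_aromatic(self):
        from gdtr.synthetic import _build_his, _build_asp, _build_phe, _X, _Y
        his = _build_his(1, np.zeros(3), -_X, _Y)
        asp = _build_asp(2, np.array([4.0, 0, 0]), _X, _Y)
        assert InteractionType.IONIC in _kinds(his, asp)
        phe = _build_phe(3, np.array([6.0, 0, 0]), _X, _Y)
        assert InteractionType.AROMATIC_AROMATIC in _kinds(his, phe)


class TestInterfaceResidues:
    def _two_res_complex(self, d):
        a = Residue("GLY", 1, atoms=[Atom("CA", "C", [0.0, 0.0, 0.0])])
        b = Residue("GLY", 1, atoms=[Atom("CA", "C", [d, 0.0, 0.0])])
        return ComplexStructure(chains=[ChainModel("A", [a]), ChainModel("B", [b])])

    def test_within_cutoff_included(self):
        side_a, side_b = interface_residues(self._two_res_complex(3.8), {"A"}, {"B"})
        assert len(side_a) == 1 and len(side_b) == 1

    def test_beyond_cutoff_excluded(self):
        with pytest.raises(ValueError):
            interface_residues(self._two_res_complex(4.2), {"A"}, {"A"})
        side_a, side_b = interface_residues(self._two_res_complex(4.2), {"A"}, {"B"})
        assert side_a == [] and side_b == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chains = []
        for cid in "AB":
            residues = [
                Residue("GLY", i + 1, atoms=[
                    Atom("CA", "C", rng.uniform(0, 18, 3)),
                    Atom("O", "O", rng.uniform(0, 18, 3)),
                ])
                for i in range(25)
            ]
            chains.append(ChainModel(cid, residues))
        s = ComplexStructure(chains=chains)
        side_a, side_b = interface_residues(s, {"A"}, {"B"}, cutoff=4.0)
        got = ({(c, r.key) for c, r in side_a}, {(c, r.key) for c, r in side_b})
        assert got == brute_force_interface(s, {"A"}, {"B"}, 4.0)


class TestContactTable:
    def test_planted_contacts_recovered_exactly(self):
        s, truth = gen_complex_fixture(
            {"IONIC": 1, "HBOND_SS": 1, "AROMATIC_AROMATIC": 1}, seed=6
        )
        table = contact_table(s, {"G"}, {"D"},
                              params=ContactParams(interface_cutoff=8.0))
        got = sorted((c.kind.value, c.res_a.author_number, c.res_b.author_number)
                     for c in table.contacts)
        expected = sorted((t["kind"], t["author_a"], t["author_b"])
                          for t in truth.truth["contacts"])
        assert got == expected

    def test_receptor_style_ionic_pairs_recovered(self):
        """Regression: His/Asp and Lys/Asp salt bridges planted across a
        V-gamma/V-delta-style interface are both typed ionic."""
        s, _ = gen_complex_fixture(
            planted=[("HIS", 40, "ASP", 119, "IONIC", 4.5),
                     ("LYS", 116, "ASP", 107, "IONIC", 4.5)],
            seed=14,
        )
        table = contact_table(s, {"G"}, {"D"},
                              params=ContactParams(interface_cutoff=8.0))
        got = {(c.res_a.author_number, c.res_b.author_number, c.kind.value)
               for c in table.contacts}
        assert got == {(40, 119, "IONIC"), (116, 107, "IONIC")}

    def test_distant_groups_give_empty_table(self):
        s, _ = gen_complex_fixture(None, seed=8)
        table = contact_table(s, {"G"}, {"D"},
                              params=ContactParams(interface_cutoff=8.0))
        assert len(table) == 0

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed):
        """Table equals exhaustive all-pairs classification over the
        brute-force interface selection."""
        kinds = {k: (seed + i) % 2 for i, k in enumerate(InteractionType)}
        s, _ = gen_complex_fixture(kinds, seed=seed)
        params = ContactParams(interface_cutoff=8.0)
        table = contact_table(s, {"G"}, {"D"}, params=params)
        sel_a, sel_b = brute_force_interface(s, {"G"}, {"D"}, params.interface_cutoff)
        expected = []
        for cid_a, res_a in ((c, r) for c in ["G"] for r in s.chain(c)):
            for cid_b, res_b in ((c, r) for c in ["D"] for r in s.chain(c)):
                if (cid_a, res_a.key) in sel_a and (cid_b, res_b.key) in sel_b:
                    for contact in classify_pair(res_a, res_b, params):
                        expected.append((res_a.key, res_b.key, contact.kind, contact.distance))
        got = [((c.res_a.author_number, c.res_a.insertion_code),
                (c.res_b.author_number, c.res_b.insertion_code), c.kind, c.distance)
               for c in table.contacts]
        assert sorted(got, key=str) == sorted(expected, key=str)

    def test_every_contact_distance_within_window(self):
        s, _ = gen_complex_fixture(1, seed=13)
        table = contact_table(s, {"G"}, {"D"}, params=ContactParams(interface_cutoff=8.0))
        assert len(table) > 0
        for c in table.contacts:
            if c.kind is InteractionType.AROMATIC_AROMATIC:
                assert 4.5 <= c.distance <= 7.0
            else:
                assert c.distance <= THRESHOLDS[c.kind]

    def test_tsv_roundtrip(self, tmp_path):
        s, _ = gen_complex_fixture({"IONIC": 2}, seed=9)
        table = contact_table(s, {"G"}, {"D"}, params=ContactParams(interface_cutoff=8.0))
        p = tmp_path / "contacts.tsv"
        table.to_tsv(p)
        back = ContactTable.from_tsv(p, groups=table.groups)
        assert len(back) == len(table)
        assert [c.kind for c in back.contacts] == [c.kind for c in table.contacts]


class TestSummarizeTable:
    def test_counts_permutation_invariant(self):
        s, _ = gen_complex_fixture(1, seed=10)
        table = contact_table(s, {"G"}, {"D"}, params=ContactParams(interface_cutoff=8.0))
        reversed_table = ContactTable(contacts=list(reversed(table.contacts)),
                                      groups=table.groups)
        assert summarize_table(table) == summarize_table(reversed_table)

    def test_empty_table_all_zero(self):
        t = ContactTable(contacts=[], groups=("A", "B"))
        summary = summarize_table(t)
        assert summary.n_contacts == 0
        assert summary.by_type == {}
        assert summary.residues_per_group == {"A": 0, "B": 0}
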