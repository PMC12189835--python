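import copy

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from scipy.spatial.transform import Rotation

from conftest import needleman_wunsch_gotoh
from gdtr.modeling import (ThreadingError, align_pair, clash_count, superpose,
                           thread_model)
from gdtr.structures import Atom, ChainModel, ComplexStructure, Residue
from gdtr.synthetic import chain_from_sequence, sc19_like_v_delta


def _transform(chain, rot, shift):
    out = copy.deepcopy(chain)
    for res in out:
        for atom in res.atoms:
            atom.xyz = rot @ atom.xyz + shift
    return out


class TestAlignPair:
    def test_identical_sequences(self):
        aln = align_pair("ACDEFGHIK", "ACDEFGHIK")
        assert aln.identity_pct == 100.0
        assert aln.coverage_pct == 100.0

    def test_identity_is_symmetric(self):
        a, b = "ACDKFGHWK", "ACDEFGYIK"
        assert align_pair(a, b).identity_pct == align_pair(b, a).identity_pct

    @pytest.mark.parametrize("seed", range(30))
    def test_score_matches_dp_oracle(self, seed):
        """Optimal global score agrees with an independent Gotoh DP on all
        short pairs."""
        rng = np.random.default_rng(seed)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(alphabet, size=rng.integers(1, 11)))
        b = "".join(rng.choice(alphabet, size=rng.integers(1, 11)))
        aln = align_pair(a, b)
        blosum = substitution_matrices.load("BLOSUM62")
        expected = needleman_wunsch_gotoh(a, b, blosum, 10.0, 0.5)
        assert aln.score == pytest.approx(expected)

    def test_known_divergence_identity(self):
        ref = "ACDEFGHIKLMNPQRSTVWY" * 2
        query = list(ref)
        for i in (0, 5, 10, 15, 20, 25, 30, 35):  # 8/40 substituted
            query[i] = "A" if ref[i] != "A" else "G"
        aln = align_pair("".join(query), ref)
        assert aln.coverage_pct == 100.0
        assert aln.identity_pct == pytest.approx(80.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "ACD")


class TestThreadModel:
    def test_self_threading_is_coordinate_identical(self):
        template = chain_from_sequence(sc19_like_v_delta(), "D")
        aln = align_pair(template.sequence(), template.sequence())
        model = thread_model(aln, template).chain
        assert model.sequence() == template.sequence()
        for mres, tres in zip(model, template):
            for ma, ta in zip(mres.atoms, tres.atoms):
                assert np.allclose(ma.xyz, ta.xyz)
        assert superpose(model, template).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_point_mutant_truncated_to_cb(self):
        template = chain_from_sequence("ACDEFGHIKL", "T")
        query = "ACDEFGHIKV"  # L -> V at the last position
        aln = align_pair(query, template.sequence())
        model = thread_model(aln, template).chain
        assert model.residues[-1].name3 == "VAL"
        names = {a.name for a in model.residues[-1].atoms}
        assert names == {"N", "CA", "C", "CB"}
        for res_m, res_t in zip(model.residues[:-1], template.residues[:-1]):
            assert res_m.name3 == res_t.name3

    def test_query_insertion_flagged_not_built(self):
        template = chain_from_sequence("ACDEFGHIKLMNPQRSTVWY", "T")
        query = "ACDEFGHIKL" + "AAAAA" + "MNPQRSTVWY"
        aln = align_pair(query, template.sequence())
        result = thread_model(aln, template)
        assert result.unmodeled_insertions  # flagged
        assert len(result.chain) == len(query) - len(result.unmodeled_insertions)

    def test_low_coverage_is_fatal(self):
        template = chain_from_sequence("ACDEF", "T")
        query = "ACDEF" + "W" * 20
        aln = align_pair(query, template.sequence())
        with pytest.raises(ThreadingError, match="template unsuitable"):
            thread_model(aln, template)


class TestSuperpose:
    def test_self_rmsd_zero(self):
        chain = chain_from_sequence("ACDEFGHIKLMNPQRSTVWY", "A")
        sup = superpose(chain, chain)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_known_rotation_recovered(self):
        chain = chain_from_sequence("ACDEFGHIKLMNPQRSTVWY" * 2, "A")
        rot = Rotation.from_euler("xyz", [0.4, -1.2, 2.2]).as_matrix()
        shift = np.array([7.0, -4.0, 11.0])
        mobile = _transform(chain, rot, shift)
        sup = superpose(mobile, chain)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, rot.T, atol=1e-6)

    def test_invariant_to_rigid_pretransform(self):
        rng = np.random.default_rng(5)
        chain = chain_from_sequence("ACDEFGHIKLMNPQRSTVWY", "A")
        noisy = copy.deepcopy(chain)
        for res in noisy:
            for atom in res.atoms:
                atom.xyz = atom.xyz + rng.normal(0, 0.4, 3)
        base = superpose(noisy, chain).rmsd
        rot = Rotation.from_euler("zyx", [1.0, 0.2, -0.5]).as_matrix()
        moved = _transform(noisy, rot, np.array([3.0, 2.0, 1.0]))
        assert superpose(moved, chain).rmsd == pytest.approx(base, abs=1e-6)

    def test_noise_rmsd_matches_simulation_oracle(self):
        """Fitted RMSD under isotropic coordinate noise tracks the
        Monte-Carlo expectation."""
        sigma = 0.5
        chain = chain_from_sequence("ACDEFGHIKLMNPQRSTVWY" * 3, "A")
        rng = np.random.default_rng(17)
        rmsds = []
        for _ in range(25):
            noisy = copy.deepcopy(chain)
            for res in noisy:
                for atom in res.atoms:
                    atom.xyz = atom.xyz + rng.normal(0, sigma, 3)
            rmsds.append(superpose(noisy, chain).rmsd)
        observed = np.mean(rmsds)
        expected = sigma * np.sqrt(3.0)  # large-N limit of the fit residual
        assert observed == pytest.approx(expected, rel=0.15)

    def test_collinear_points_fatal(self):
        residues = [
            Residue("GLY", i + 1, atoms=[Atom("CA", "C", [3.8 * i, 0.0, 0.0])])
            for i in range(5)
        ]
        line = ChainModel("L", residues)
        with pytest.raises(ValueError, match="degenerate"):
            superpose(line, line)

    def test_requires_three_pairs(self):
        chain = chain_from_sequence("ACD", "A")
        with pytest.raises(ValueError):
            superpose(chain, chain, pairing=[(0, 0), (1, 1)])


class TestClashCount:
    def test_two_close_atoms_in_different_residues(self):
        s = ComplexStructure(chains=[
            ChainModel("A", [Residue("GLY", 1, atoms=[Atom("CA", "C", [0, 0, 0])])]),
            ChainModel("B", [Residue("GLY", 1, atoms=[Atom("CA", "C", [1.0, 0, 0])])]),
        ])
        assert clash_count(s) == 1

    def test_clean_chain_has_no_clashes(self):
        chain = chain_from_sequence("ACDEFGHIKLMNPQRSTVWY", "A")
        assert clash_count(chain) == 0

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_planted_overlaps_counted(self, k):
        chain = chain_from_sequence("ACDEFGHIKLMNPQRSTVWY" * 2, "A")
        z1 = ChainModel("Y", [
            Residue("GLY", i + 1, atoms=[Atom("CA", "C", [200.0 + 10 * i, 0, 0])])
            for i in range(k)
        ])
        z2 = ChainModel("Z", [
            Residue("GLY", i + 1, atoms=[Atom("CA", "C", [200.9 + 10 * i, 0, 0])])
            for i in range(k)
        ])
        s = ComplexStructure(chains=[chain, z1, z2])
        assert clash_count(s) == k

    def test_adjacent_backbone_contacts_excluded(self):
        # consecutive residues with C(i)-N(i+1) at bond distance
        residues = [
            Residue("GLY", 1, atoms=[Atom("C", "C", [0.0, 0.0, 0.0])]),
            Residue("GLY", 2, atoms=[Atom("N", "N", [1.33, 0.0, 0.0])]),
        ]
        assert clash_count(ChainModel("A", residues)) == 0
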