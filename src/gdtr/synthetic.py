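"""Synthetic inputs with ground-truth records for every generated artifact.

Everything the pipeline consumes can be generated here without network
access: rearranged V-(D)-J nucleotide clones with known block composition,
V- and G-domain amino-acid sequences carrying the conserved IMGT anchors,
and small 3D structures with residue pairs planted at controlled geometries
for each interaction class.  Each generator returns its artifact together
with a :class:`TruthRecord` holding the full answer key, and the same seed
reproduces byte-identical output.

The module also ships fixed fixture sequences emulating the two clones the
contact tables describe: a V-GAMMA domain with CDR-IMGT lengths [6.8.15]
and a V-DELTA domain with [7.3.37] whose very long CDR3 occupies the
111.1-111.12 / 112.12-112.1 insertion positions.  These are synthetic
constructions (the real cDNA translations are not redistributed here) with
the tabulated interface residues planted at their IMGT positions.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.transform import Rotation

from .interface import InteractionType
from .junctions import GermlineSegment, RearrangedClone
from .structures import Atom, ChainModel, ComplexStructure, Residue

__all__ = [
    "TruthRecord",
    "gen_rearrangement",
    "gen_domain_sequence",
    "gen_interaction_fixture",
    "gen_complex_fixture",
    "rts88_like_v_gamma",
    "sc19_like_v_delta",
    "default_germline",
    "chain_from_sequence",
    "DEFAULT_CONTACT_DISTANCES",
]


@dataclass
class TruthRecord:
    generator: str
    seed: int
    parameters: dict
    truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"generator": self.generator, "seed": self.seed,
             "parameters": self.parameters, "truth": self.truth},
            sort_keys=True, indent=2,
        )


def _rng(seed: int, stream: str) -> np.random.Generator:
    """One named, independent pseudo-random stream per generator."""
    return np.random.default_rng([zlib.crc32(stream.encode()), seed])


# ---------------------------------------------------------------------------
# fixture V-domain sequences (synthetic stand-ins for the two clones whose
# interface the contact tables tabulate)

_FR1_G = "AQKVTQAQSSVSMPVRKAVTLNCLYE"           # 26, 1st-CYS 23
_CDR1_G = "TGDSNY"                              # [6]: 27-29 + 36-38
_FR2_G = "VHWYQFPGQGPEGRLIY"                    # 17, TRP 41
_CDR2_G = "SDGSVTKE"                            # [8]: 56-59 + 62-65
_FR3_G = "NKERFTATVNKSSSEAKSFSLTISDTQPALNEDSGTYLC"  # 39, 2nd-CYS 104
_CDR3_G = "ALERDTLYTSAWRKV"                     # [15]: inserts 111.1, 112.1
_FR4_G = "FGSGTKLIVTD"                          # 11, J-PHE 118

_FR1_D = "AQKVTQTQSSMSVEGKTVTLNCAYE"            # 25 (FR1 position 10 absent)
_CDR1_D = "GDWSVGT"                             # [7]: 27-30 + 36-38
_FR2_D = "LIWYVQYPGEGPQFLLR"                    # 17
_CDR2_D = "DTS"                                 # [3]: 56, 57, 65
_FR3_D = "KGSNKGFEATVNKTAKSFSTLISETQPEDSLGDKATYFC"  # 39
_CDR3_D = "ALDGRTLSYGRWTRLDWTSATSLTAWTSLTARTSLTV"   # [37]
_FR4_D = "FGTGTKLEVTP"                          # 11


def rts88_like_v_gamma() -> str:
    """Synthetic V-GAMMA fixture, CDR-IMGT lengths [6.8.15]."""
    seq = _FR1_G + _CDR1_G + _FR2_G + _CDR2_G + _FR3_G + _CDR3_G + _FR4_G
    assert len(seq) == 122
    return seq


def sc19_like_v_delta() -> str:
    """Synthetic V-DELTA fixture, CDR-IMGT lengths [7.3.37]."""
    seq = _FR1_D + _CDR1_D + _FR2_D + _CDR2_D + _FR3_D + _CDR3_D + _FR4_D
    assert len(seq) == 139
    return seq


# ---------------------------------------------------------------------------
# germline references (synthetic) and rearrangement generator

_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def _backtranslate(aa: str) -> str:
    return "".join(_CODON[a] for a in aa)


#: Synthetic D segments: short, mutually distinguishable at full length,
#: free of stop triplets in any frame.
_D_SEGMENTS = {
    "TRDD1": "CCTTCCTACACC",
    "TRDD2": "GGGATACGGAGG",
    "TRDD3": "ACTGGGGGATAC",
    "TRDD4": "CGTCTTGGGACC",
    "TRDD5": "GGCACTACCTTC",
    "TRDD6": "TTCGCGGGAACT",
}

_V3_AA = "ALD"        # germline 3'V-REGION extending past the 2nd-CYS
_J5_AA = "TSLTV"      # germline 5'J-REGION preceding J-PHE 118


def default_germline() -> tuple[GermlineSegment, GermlineSegment, list[GermlineSegment]]:
    """Synthetic TRD germline set: V (through the 2nd-CYS plus a short 3'
    region), J (5' region, J-PHE codon and FR4) and six D segments."""
    v_aa = _FR1_D + _CDR1_D + _FR2_D + _CDR2_D + _FR3_D
    v = GermlineSegment("TRDV1", "V", _backtranslate(v_aa) + _backtranslate(_V3_AA))
    j = GermlineSegment("TRDJ4", "J", _backtranslate(_J5_AA) + _backtranslate(_FR4_D))
    d_refs = [GermlineSegment(name, "D", nt) for name, nt in _D_SEGMENTS.items()]
    return v, j, d_refs


def _has_spurious_match(
    middle: str,
    planted: list[tuple[int, int]],
    d_refs: list[GermlineSegment],
    min_match: int,
    max_mismatch: int,
) -> bool:
    """True if some D-match window would make the planted decomposition
    ambiguous.

    Windows overlapping a planted block are harmless (the full-length
    planted match wins the greedy selection and occupies them), so only two
    kinds of window are flagged: any qualifying window lying entirely
    outside the planted spans (it would surface as a false D block in PN
    territory), and any exact full-length germline occurrence that is not
    itself a planted span (it could outrank a planted block)."""
    def overlaps(s: int, e: int) -> bool:
        return any(s < pe and e > ps for ps, pe in planted)

    n = len(middle)
    for ref in d_refs:
        d = ref.nt_seq
        for j_off in range(n):
            for d_off in range(len(d)):
                mism = 0
                for k in range(min(n - j_off, len(d) - d_off)):
                    if middle[j_off + k] != d[d_off + k]:
                        mism += 1
                        if mism > max_mismatch:
                            break
                    length = k + 1
                    if length >= min_match and not overlaps(j_off, j_off + length):
                        return True
                    if (length == len(d) and mism == 0
                            and (j_off, j_off + length) not in planted):
                        return True
    return False


_STOPS = ("TAA", "TAG", "TGA")


def _window_ending_matches(s: list[str], d_refs, min_match: int, max_mismatch: int) -> bool:
    """True if some window ending at the last base of ``s`` matches a
    D-segment stretch of length >= min_match with <= max_mismatch."""
    n = len(s)
    for ref in d_refs:
        d = ref.nt_seq
        for length in range(min_match, min(n, len(d)) + 1):
            tail = s[n - length:]
            for d_off in range(len(d) - length + 1):
                if sum(a != b for a, b in zip(tail, d[d_off:d_off + length])) <= max_mismatch:
                    return True
    return False


def _clean_pn(rng: np.random.Generator, length: int, d_refs,
              min_match: int, max_mismatch: int) -> str | None:
    """Random PN stretch guaranteed free of D-match windows: built base by
    base, each candidate base vetted against every window ending at it."""
    for _restart in range(50):
        s: list[str] = []
        ok = True
        for _ in range(length):
            placed = False
            for b in rng.permutation(list("ACGT")):
                s.append(str(b))
                if not _window_ending_matches(s, d_refs, min_match, max_mismatch):
                    placed = True
                    break
                s.pop()
            if not placed:
                ok = False
                break
        if ok:
            return "".join(s)
    return None


def _translate_frame0(nt: str) -> str:
    from Bio.Seq import Seq
    nt = nt[: len(nt) - len(nt) % 3]
    return str(Seq(nt).translate())


def gen_rearrangement(
    v_ref: GermlineSegment | None = None,
    j_ref: GermlineSegment | None = None,
    d_refs: list[GermlineSegment] | None = None,
    n_d: int = 2,
    pn_len_range: tuple[int, int] = (0, 6),
    mutation_rate: float = 0.0,
    seed: int = 0,
    target_cdr3_aa: int | None = None,
    name: str | None = None,
    tissue: str = "spleen",
    min_match: int = 5,
    max_mismatch: int = 1,
) -> tuple[RearrangedClone, TruthRecord]:
    """Generate a productive V-(D)-J rearrangement with known composition.

    The clone is 3'V + alternating PN/D blocks + 5'J, in frame with no
    internal stop, and with no D-segment match window outside the planted
    blocks (so the decomposition recorded in the truth is unique).  Point
    mutations are applied inside D blocks only, emulating the substitution-
    bearing D matches of hypermutated junction repertoires.
    """
    if v_ref is None or j_ref is None or d_refs is None:
        dv, dj, dd = default_germline()
        v_ref = v_ref or dv
        j_ref = j_ref or dj
        d_refs = d_refs if d_refs is not None else dd
    if not 0 <= n_d <= min(5, len(d_refs)):
        raise ValueError("n_d must be in 0..5 and not exceed the D references")
    rng = _rng(seed, "rearrangement")

    from .junctions import _germline_j_5prime, _germline_v_3prime
    v3 = _germline_v_3prime(v_ref)
    j5 = _germline_j_5prime(j_ref)
    genes = sorted(rng.choice([r.gene_name for r in d_refs], size=n_d, replace=False))
    by_name = {r.gene_name: r for r in d_refs}
    d_lens = [len(by_name[g].nt_seq) for g in genes]

    lo, hi = pn_len_range
    for attempt in range(200):
        if target_cdr3_aa is not None:
            pn_total = 3 * target_cdr3_aa - len(v3) - len(j5) - sum(d_lens)
            if pn_total < 0:
                raise ValueError("target CDR3 length too short for the requested D count")
            cuts = np.sort(rng.integers(0, pn_total + 1, size=n_d))
            pn_lens = np.diff(np.concatenate([[0], cuts, [pn_total]])).tolist()
        else:
            pn_lens = rng.integers(lo, hi + 1, size=n_d + 1).tolist()
            total = len(v3) + sum(pn_lens) + sum(d_lens) + len(j5)
            pn_lens[-1] += (-total) % 3
        check_unique = mutation_rate == 0.0
        mutated_sites: list[int] = []

        middle: str | None = ""
        planted: list[tuple[int, int]] = []
        for i in range(n_d + 1):
            pn = (_clean_pn(rng, pn_lens[i], d_refs, min_match, max_mismatch)
                  if check_unique else
                  "".join(rng.choice(list("ACGT"), size=pn_lens[i])))
            if pn is None:
                middle = None
                break
            middle += pn
            if i < n_d:
                d_nt = list(by_name[genes[i]].nt_seq)
                for k in range(1, len(d_nt) - 1):
                    if rng.random() < mutation_rate:
                        d_nt[k] = rng.choice([b for b in "ACGT" if b != d_nt[k]])
                        mutated_sites.append(len(middle) + k)
                planted.append((len(middle), len(middle) + len(d_nt)))
                middle += "".join(d_nt)
        if middle is None:
            continue

        nt = v_ref.nt_seq + middle + j_ref.nt_seq
        aa = _translate_frame0(nt)
        if "*" in aa:
            continue
        # the first J-motif must be the planted one (a chance F/W-G-X-G
        # inside the junction would shift the delimitation)
        from .junctions import locate_anchors
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                c104, j118 = locate_anchors(aa)
        except ValueError:
            continue
        exp_c104 = len(v_ref.nt_seq) // 3 - len(v3) // 3 - 1
        exp_j118 = exp_c104 + 1 + (len(v3) + len(middle) + len(j5)) // 3
        if (c104, j118) != (exp_c104, exp_j118):
            continue
        if mutation_rate == 0.0 and _has_spurious_match(
            middle, planted, d_refs, min_match, max_mismatch
        ):
            continue
        break
    else:
        raise RuntimeError("could not compose a productive junction in 200 attempts")

    clone = RearrangedClone(
        name=name or f"SYN{seed}", nt_seq=nt, tissue=tissue, reading_frame=0, locus="TRD"
    )
    cdr3_len = (len(v3) + len(middle) + len(j5)) // 3
    blocks = [{"origin": "3'V", "start": 0, "end": len(v3)}] if v3 else []
    pos = len(v3)
    for i, gene in enumerate(genes):
        if pn_lens[i]:
            blocks.append({"origin": "PN", "start": pos, "end": pos + pn_lens[i]})
            pos += pn_lens[i]
        d_len = d_lens[i]
        blocks.append({"origin": f"D:{gene}", "start": pos, "end": pos + d_len})
        pos += d_len
    if pn_lens[-1]:
        blocks.append({"origin": "PN", "start": pos, "end": pos + pn_lens[-1]})
        pos += pn_lens[-1]
    if j5:
        blocks.append({"origin": "5'J", "start": pos, "end": pos + len(j5)})
    truth = TruthRecord(
        generator="gen_rearrangement", seed=seed,
        parameters={"n_d": n_d, "pn_len_range": list(pn_len_range),
                    "mutation_rate": mutation_rate, "target_cdr3_aa": target_cdr3_aa},
        truth={"d_genes": [str(g) for g in genes], "blocks": blocks,
               "cdr3_length_aa": cdr3_len, "cdr3_nt": v3 + middle + j5,
               "mutated_sites": sorted(m + len(v3) for m in mutated_sites),
               "anchors": {"c104_aa_index": exp_c104, "j118_aa_index": exp_j118}},
    )
    return clone, truth


# ---------------------------------------------------------------------------
# domain sequence generator

_CDR_POOL = list("ADEGHIKLNPQRSTVY")  # no C/W/F: keeps anchors unambiguous


def gen_domain_sequence(
    kind: str = "V",
    cdr_lengths: tuple[int, int, int] = (6, 8, 15),
    fr1_absent: tuple[int, ...] = (),
    g_reference=None,
    g_insertion: tuple[str, str] | None = None,
    n_substitutions: int = 0,
    seed: int = 0,
) -> tuple[str, TruthRecord]:
    """Generate a domain amino-acid sequence with planted anchors.

    ``kind="V"``: framework scaffolds with the conserved anchors (1st-CYS
    23, TRP 41, 2nd-CYS 104, J-PHE 118 + F-G-X-G) and random CDR loops of
    the requested lengths.  ``kind="G"``: the reference profile sequence
    with ``n_substitutions`` random substitutions and an optional letter
    insertion ``(after_position, amino_acid)`` such as ("72", "S").
    """
    rng = _rng(seed, "domain")
    if kind == "V":
        l1, l2, l3 = cdr_lengths
        fr1 = "".join(ch for i, ch in enumerate(_FR1_G, start=1) if i not in fr1_absent)
        cdr1 = "".join(rng.choice(_CDR_POOL, size=l1))
        cdr2 = "".join(rng.choice(_CDR_POOL, size=l2))
        cdr3 = "".join(rng.choice(_CDR_POOL, size=l3))
        seq = fr1 + cdr1 + _FR2_G + cdr2 + _FR3_G + cdr3 + _FR4_G
        ic23 = fr1.index("C", 20)
        iw41 = len(fr1) + l1 + 2
        ic104 = len(fr1) + l1 + 17 + l2 + 38
        truth = {"cdr_lengths": list(cdr_lengths), "fr1_absent": list(fr1_absent),
                 "anchors": {"c23": ic23, "w41": iw41, "c104": ic104, "f118": ic104 + 1 + l3}}
        record = TruthRecord("gen_domain_sequence", seed,
                             {"kind": "V", "cdr_lengths": list(cdr_lengths)}, truth)
        return seq, record
    if kind == "G":
        if g_reference is None:
            raise ValueError("kind='G' requires a reference profile")
        seq = list(g_reference.sequence)
        sites = rng.choice(len(seq), size=min(n_substitutions, len(seq)), replace=False)
        for i in sites:
            seq[i] = rng.choice([a for a in _CDR_POOL if a != seq[i]])
        inserted_at = None
        if g_insertion is not None:
            after, aa = g_insertion
            idx = g_reference.positions.index(after)
            seq.insert(idx + 1, aa)
            inserted_at = after
        truth = {"substituted_sites": sorted(int(i) for i in sites),
                 "insertion_after": inserted_at,
                 "insertion_aa": g_insertion[1] if g_insertion else None}
        record = TruthRecord("gen_domain_sequence", seed,
                             {"kind": "G", "reference": g_reference.kind}, truth)
        return "".join(seq), record
    raise ValueError("kind must be 'V' or 'G'")


# ---------------------------------------------------------------------------
# planted-geometry structure fixtures

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


def _mk(name: str, element: str, xyz: np.ndarray) -> Atom:
    return Atom(name=name, element=element, xyz=np.asarray(xyz, dtype=float))


def _tail(p: np.ndarray, u: np.ndarray, v: np.ndarray, a0: float) -> list[Atom]:
    """Generic backbone placed ``a0`` A behind the defining feature."""
    return [
        _mk("CA", "C", p + a0 * u),
        _mk("N", "N", p + (a0 + 1.4) * u + 0.5 * v),
        _mk("C", "C", p + (a0 + 0.5) * u - 1.2 * v),
        _mk("O", "O", p + (a0 + 1.6) * u - 1.8 * v),
    ]


def _ring_atoms(names: tuple[str, ...], centroid: np.ndarray, v: np.ndarray,
                w: np.ndarray, radius: float = 1.39) -> list[Atom]:
    out = []
    for k, name in enumerate(names):
        ang = 2.0 * np.pi * k / len(names)
        elem = "N" if name.startswith("N") else "C"
        out.append(_mk(name, elem, centroid + radius * (np.cos(ang) * v + np.sin(ang) * w)))
    return out


def _build_arg(num: int, p, u, v) -> Residue:
    atoms = [
        _mk("NH1", "N", p), _mk("CZ", "C", p + 1.2 * u),
        _mk("NH2", "N", p + 1.2 * u + 1.9 * v), _mk("NE", "N", p + 2.4 * u),
        _mk("CD", "C", p + 3.6 * u), _mk("CG", "C", p + 4.8 * u),
        _mk("CB", "C", p + 6.0 * u),
    ] + _tail(p, u, v, 7.4)
    return Residue("ARG", num, atoms=atoms)


def _build_asp(num: int, p, u, v) -> Residue:
    atoms = [
        _mk("OD1", "O", p), _mk("CG", "C", p + 1.2 * u),
        _mk("OD2", "O", p + 1.9 * u + 1.0 * v), _mk("CB", "C", p + 2.6 * u),
    ] + _tail(p, u, v, 4.0)
    return Residue("ASP", num, atoms=atoms)


def _build_ser(num: int, p, u, v) -> Residue:
    atoms = [_mk("OG", "O", p), _mk("CB", "C", p + 1.4 * u)] + _tail(p, u, v, 2.9)
    return Residue("SER", num, atoms=atoms)


def _build_gly_o(num: int, p, u, v) -> Residue:
    atoms = [_mk("O", "O", p), _mk("C", "C", p + 1.2 * u),
             _mk("CA", "C", p + 2.7 * u), _mk("N", "N", p + 4.1 * u)]
    return Residue("GLY", num, atoms=atoms)


def _build_gly_n(num: int, p, u, v) -> Residue:
    atoms = [_mk("N", "N", p), _mk("CA", "C", p + 1.5 * u),
             _mk("C", "C", p + 2.9 * u + 0.5 * v), _mk("O", "O", p + 3.4 * u + 1.6 * v)]
    return Residue("GLY", num, atoms=atoms)


def _build_phe(num: int, p, u, v) -> Residue:
    w = np.cross(u, v)
    ring = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    atoms = _ring_atoms(ring, p, v, w) + [_mk("CB", "C", p + 1.2 * u)] + _tail(p, u, v, 2.7)
    return Residue("PHE", num, atoms=atoms)


def _build_met(num: int, p, u, v) -> Residue:
    atoms = [_mk("SD", "S", p), _mk("CE", "C", p + 1.8 * u + 0.3 * v),
             _mk("CG", "C", p + 1.8 * u - 0.8 * v), _mk("CB", "C", p + 3.2 * u)]
    return Residue("MET", num, atoms=atoms + _tail(p, u, v, 4.6))


def _build_lys(num: int, p, u, v) -> Residue:
    atoms = [_mk("NZ", "N", p), _mk("CE", "C", p + 1.5 * u), _mk("CD", "C", p + 3.0 * u),
             _mk("CG", "C", p + 4.4 * u), _mk("CB", "C", p + 5.8 * u)]
    return Residue("LYS", num, atoms=atoms + _tail(p, u, v, 7.2))


def _build_leu(num: int, p, u, v) -> Residue:
    atoms = [_mk("CD1", "C", p), _mk("CG", "C", p + 1.5 * u),
             _mk("CD2", "C", p + 1.5 * u + 1.3 * v), _mk("CB", "C", p + 3.0 * u)]
    return Residue("LEU", num, atoms=atoms + _tail(p, u, v, 4.4))


def _build_val(num: int, p, u, v) -> Residue:
    atoms = [_mk("CG1", "C", p), _mk("CB", "C", p + 1.5 * u),
             _mk("CG2", "C", p + 1.5 * u + 1.3 * v)]
    return Residue("VAL", num, atoms=atoms + _tail(p, u, v, 3.0))


def _build_his(num: int, p, u, v) -> Residue:
    w = np.cross(u, v)
    ring = ("CG", "ND1", "CE1", "NE2", "CD2")
    atoms = _ring_atoms(ring, p, v, w, radius=1.17) + [_mk("CB", "C", p + 1.2 * u)]
    return Residue("HIS", num, atoms=atoms + _tail(p, u, v, 2.7))


_Builder = Callable[[int, np.ndarray, np.ndarray, np.ndarray], Residue]

#: (builder_a, builder_b, default defining distance) per interaction type.
_PAIR_BUILDERS: dict[InteractionType, tuple[_Builder, _Builder, float]] = {
    InteractionType.IONIC: (_build_arg, _build_asp, 4.5),
    InteractionType.HBOND_SS: (_build_ser, _build_ser, 3.0),
    InteractionType.HBOND_MS: (_build_ser, _build_gly_o, 3.0),
    InteractionType.HBOND_MM: (_build_gly_n, _build_gly_o, 3.0),
    InteractionType.AROMATIC_AROMATIC: (_build_phe, _build_phe, 6.0),
    InteractionType.AROMATIC_SULFUR: (_build_phe, _build_met, 4.5),
    InteractionType.CATION_PI: (_build_lys, _build_phe, 4.5),
    InteractionType.HYDROPHOBIC: (_build_leu, _build_val, 4.5),
}

DEFAULT_CONTACT_DISTANCES = {k: d for k, (_, _, d) in _PAIR_BUILDERS.items()}

# For HIS-involving ionic plants (the His/Asp pairs of the contact tables).
_NAMED_BUILDERS: dict[str, _Builder] = {
    "ARG": _build_arg, "ASP": _build_asp, "SER": _build_ser, "PHE": _build_phe,
    "MET": _build_met, "LYS": _build_lys, "LEU": _build_leu, "VAL": _build_val,
    "HIS": _build_his,
}


def _scatter(structure: ComplexStructure, rng: np.random.Generator) -> None:
    """Apply one rigid transform to the whole structure (distances kept)."""
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-30.0, 30.0, size=3)
    for chain in structure.chains:
        for res in chain:
            for atom in res.atoms:
                atom.xyz = rot @ atom.xyz + shift


def _decoy_chain(chain_id: str, origin: np.ndarray, n: int = 2) -> ChainModel:
    residues = [
        _build_gly_o(900 + i, origin + np.array([6.0 * i, 0.0, 0.0]), _X, _Y)
        for i in range(n)
    ]
    return ChainModel(chain_id=chain_id, residues=residues)


def gen_interaction_fixture(
    kind: InteractionType | str,
    distance: float | None = None,
    seed: int = 0,
) -> tuple[ComplexStructure, TruthRecord]:
    """Two-chain mini structure with one residue pair of the requested type
    planted at the requested defining distance; decoys sit >= 10 A away."""
    kind = InteractionType(kind)
    build_a, build_b, default_d = _PAIR_BUILDERS[kind]
    d = default_d if distance is None else float(distance)
    rng = _rng(seed, "interaction")
    res_a = build_a(10, np.zeros(3), -_X, _Y)
    res_b = build_b(10, d * _X, _X, _Y)
    chain_a = ChainModel("A", residues=[res_a, _build_gly_o(11, np.array([0.0, 15.0, 0.0]), _Y, _Z)])
    chain_b = ChainModel("B", residues=[res_b, _build_gly_o(11, np.array([0.0, -15.0, 0.0]), -_Y, _Z)])
    s = ComplexStructure(chains=[chain_a, chain_b], source="synthetic",
                         title=f"planted {kind.value} at {d:.2f} A")
    _scatter(s, rng)
    truth = TruthRecord(
        "gen_interaction_fixture", seed,
        {"kind": kind.value, "distance": d},
        {"res_a": ("A", 10), "res_b": ("B", 10), "kind": kind.value, "distance": d},
    )
    return s, truth


def gen_complex_fixture(
    n_contacts: dict[InteractionType | str, int] | int | None = None,
    seed: int = 0,
    between: tuple[str, str] = ("G", "D"),
    planted: list[tuple[str, int, str, int, InteractionType | str, float]] | None = None,
) -> tuple[ComplexStructure, TruthRecord]:
    """Four-chain toy complex (receptor chains G and D, presenter C, light
    chain B) with planted inter-chain contacts and a full expected answer
    table in the truth record.

    ``n_contacts`` maps interaction type to a count (an int means that many
    of every type); ``planted`` optionally gives explicit plants as
    (res_name_a, number_a, res_name_b, number_b, kind, distance) tuples.
    The planted pairs sit between the ``between`` chains at their default
    mid-window distances, spaced far apart; the other chains are distant
    decoys, so with no plants every group pair is beyond every threshold.
    """
    rng = _rng(seed, "complex")
    if n_contacts is None:
        n_contacts = {}
    if isinstance(n_contacts, int):
        n_contacts = {k: n_contacts for k in InteractionType}
    plants: list[tuple[_Builder, str, _Builder, str, InteractionType, float]] = []
    for kind, count in n_contacts.items():
        kind = InteractionType(kind)
        ba, bb, d = _PAIR_BUILDERS[kind]
        for _ in range(count):
            plants.append((ba, None, bb, None, kind, d))
    for name_a, num_a, name_b, num_b, kind, d in planted or []:
        plants.append((_NAMED_BUILDERS[name_a], num_a, _NAMED_BUILDERS[name_b], num_b,
                       InteractionType(kind), float(d)))

    chain_a_res, chain_b_res, expected = [], [], []
    for k, (ba, num_a, bb, num_b, kind, d) in enumerate(plants):
        base = np.array([0.0, 30.0 * k, 0.0])
        na = num_a if num_a is not None else 100 + k
        nb = num_b if num_b is not None else 100 + k
        chain_a_res.append(ba(na, base, -_X, _Y))
        chain_b_res.append(bb(nb, base + d * _X, _X, _Y))
        expected.append({"chain_a": between[0], "author_a": na,
                         "chain_b": between[1], "author_b": nb,
                         "kind": kind.value, "distance": d})
    far = 30.0 * max(1, len(plants))
    chains = {
        between[0]: ChainModel(between[0], residues=chain_a_res or
                               [_build_gly_o(1, np.array([0.0, 0.0, 60.0]), _Z, _Y)]),
        between[1]: ChainModel(between[1], residues=chain_b_res or
                               [_build_gly_o(1, np.array([0.0, 0.0, -60.0]), -_Z, _Y)]),
    }
    remaining = [c for c in ("G", "D", "C", "B") if c not in chains]
    offsets = [np.array([120.0, far, 0.0]), np.array([-120.0, -far, 0.0])]
    for cid, off in zip(remaining, offsets):
        chains[cid] = _decoy_chain(cid, off)
    s = ComplexStructure(chains=[chains[c] for c in ("G", "D", "C", "B")],
                         source="synthetic", title="planted toy complex")
    _scatter(s, rng)
    truth = TruthRecord(
        "gen_complex_fixture", seed,
        {"n_contacts": {str(k): v for k, v in (n_contacts or {}).items()},
         "between": list(between)},
        {"contacts": expected, "recommended_interface_cutoff": 8.0},
    )
    return s, truth


def chain_from_sequence(seq: str, chain_id: str = "A", start: int = 1) -> ChainModel:
    """Extended poly-residue chain (N, CA, C per residue along x) whose
    sequence and author numbering are the only meaningful features."""
    from .modeling import _ONE_TO_THREE

    residues = []
    for i, aa in enumerate(seq):
        x = 3.8 * i
        y = 1.0 * (i % 2)          # zigzag keeps the CA trace non-collinear
        z = 0.7 * (i % 3)
        atoms = [
            _mk("N", "N", np.array([x - 1.2, y + 0.6, z])),
            _mk("CA", "C", np.array([x, y, z])),
            _mk("C", "C", np.array([x + 1.2, y + 0.6, z])),
        ]
        residues.append(Residue(_ONE_TO_THREE.get(aa.upper(), "UNK"), start + i, atoms=atoms))
    return ChainModel(chain_id=chain_id, residues=residues)
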