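"""Template-based comparative modeling: global alignment, backbone
threading, Kabsch superposition and a simple steric clash counter.

Threading copies template backbone coordinates onto query residues along a
global sequence alignment; identical residues keep the full template side
chain, substituted residues are truncated to CB (template CB, or an ideal
tetrahedral CB when the template has none).  Query insertions relative to
the template are flagged, not rebuilt: loop modeling is deliberately out of
scope, so downstream contact analysis must tolerate the flagged gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .structures import Atom, ChainModel, ComplexStructure, Residue, three_to_one

__all__ = [
    "TemplateAlignment",
    "Superposition",
    "ThreadingResult",
    "ThreadingError",
    "align_pair",
    "thread_model",
    "superpose",
    "apply_superposition",
    "clash_count",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_BACKBONE = ("N", "CA", "C", "O")


class ThreadingError(ValueError):
    """Raised when a template cannot support the requested model."""


@dataclass
class TemplateAlignment:
    query_seq: str
    template_seq: str
    aligned_pairs: list[tuple[int, int]]
    identity_pct: float
    coverage_pct: float
    score: float = 0.0

    def __post_init__(self) -> None:
        for (q0, t0), (q1, t1) in zip(self.aligned_pairs, self.aligned_pairs[1:]):
            if not (q1 > q0 and t1 > t0):
                raise ValueError("aligned_pairs must be strictly increasing in both coordinates")
        if not (0 <= self.identity_pct <= 100 and 0 <= self.coverage_pct <= 100):
            raise ValueError("identity and coverage must be percentages")


def align_pair(
    query: str,
    template: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> TemplateAlignment:
    """Optimal global alignment of two amino-acid sequences.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  Identity
    is computed over aligned (ungapped) pairs; coverage is the fraction of
    query residues aligned.
    """
    if not query or not template:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(query.upper(), template.upper())[0]
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (ts, _te) in zip(*aln.aligned):
        pairs += [(qs + k, ts + k) for k in range(qe - qs)]
    n_id = sum(query[q].upper() == template[t].upper() for q, t in pairs)
    identity = 100.0 * n_id / len(pairs) if pairs else 0.0
    coverage = 100.0 * len(pairs) / len(query)
    return TemplateAlignment(
        query_seq=query.upper(),
        template_seq=template.upper(),
        aligned_pairs=pairs,
        identity_pct=identity,
        coverage_pct=coverage,
        score=float(aln.score),
    )


def _ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal tetrahedral CB position from backbone N, CA, C."""
    b1 = ca - n
    b2 = ca - c
    bisector = b1 / np.linalg.norm(b1) + b2 / np.linalg.norm(b2)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(b2, b1)
    perp /= np.linalg.norm(perp)
    # 1.53 A bond, ~50 deg out of the N-CA-C plane along the bisector
    direction = np.cos(np.deg2rad(37.6)) * bisector + np.sin(np.deg2rad(37.6)) * perp
    return ca + 1.53 * direction


@dataclass
class ThreadingResult:
    """A threaded chain plus the query positions left unmodeled."""

    chain: ChainModel
    unmodeled_insertions: list[int] = field(default_factory=list)


def thread_model(aln: TemplateAlignment, template_chain: ChainModel) -> ThreadingResult:
    """Build a query model on a template chain along a global alignment.

    The output chain is numbered 1..n by query position; query residues
    with no template counterpart are absent from the chain and flagged in
    ``unmodeled_insertions``.
    """
    if aln.coverage_pct < 60.0:
        raise ThreadingError(
            f"template unsuitable: only {aln.coverage_pct:.0f}% of the query aligned (< 60%)"
        )
    if len(aln.template_seq) != len(template_chain):
        raise ThreadingError(
            f"alignment template sequence ({len(aln.template_seq)} aa) does not match "
            f"template chain ({len(template_chain)} residues)"
        )
    aligned_q = dict(aln.aligned_pairs)
    residues: list[Residue] = []
    unmodeled: list[int] = []
    for qi, q_aa in enumerate(aln.query_seq):
        ti = aligned_q.get(qi)
        if ti is None:
            unmodeled.append(qi + 1)
            continue
        t_res = template_chain.residues[ti]
        backbone = {name: t_res.atom(name) for name in _BACKBONE}
        if backbone["N"] is None or backbone["CA"] is None or backbone["C"] is None:
            raise ThreadingError(
                f"template residue {t_res.author_number} has an incomplete backbone"
            )
        name3 = _ONE_TO_THREE.get(q_aa, "UNK")
        if three_to_one(t_res.name3) == q_aa:
            atoms = [Atom(a.name, a.element, a.xyz.copy()) for a in t_res.atoms
                     if not a.is_hydrogen]
        else:
            atoms = [Atom(a.name, a.element, backbone[a_name].xyz.copy())
                     for a_name in _BACKBONE
                     if (a := backbone[a_name]) is not None]
            if name3 != "GLY":
                cb = t_res.atom("CB")
                cb_xyz = cb.xyz.copy() if cb is not None else _ideal_cb(
                    backbone["N"].xyz, backbone["CA"].xyz, backbone["C"].xyz
                )
                atoms.append(Atom("CB", "C", cb_xyz))
        residues.append(Residue(name3=name3, author_number=qi + 1, atoms=atoms))
    chain = ChainModel(chain_id=template_chain.chain_id, residues=residues,
                       molecule_label=f"model on {template_chain.molecule_label or 'template'}")
    return ThreadingResult(chain=chain, unmodeled_insertions=unmodeled)


# ---------------------------------------------------------------------------
# superposition

@dataclass
class Superposition:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def transform(self, xyz: np.ndarray) -> np.ndarray:
        return xyz @ self.rotation.T + self.translation


def _ca_coords(chain: ChainModel, indices: list[int]) -> np.ndarray:
    out = []
    for i in indices:
        ca = chain.residues[i].atom("CA")
        if ca is None:
            raise ValueError(f"residue index {i} has no CA atom")
        out.append(ca.xyz)
    return np.array(out)


def superpose(
    mobile: ChainModel,
    reference: ChainModel,
    pairing: list[tuple[int, int]] | None = None,
    atoms: str = "CA",
) -> Superposition:
    """Least-squares (Kabsch) rigid superposition of paired CA atoms.

    ``pairing`` lists (mobile residue index, reference residue index);
    by default residues are paired in order up to the shorter chain.
    """
    if atoms != "CA":
        raise ValueError("only CA superposition is supported")
    if pairing is None:
        n = min(len(mobile), len(reference))
        pairing = [(i, i) for i in range(n)]
    if len(pairing) < 3:
        raise ValueError("at least 3 atom pairs are required")
    x = _ca_coords(mobile, [p[0] for p in pairing])
    y = _ca_coords(reference, [p[1] for p in pairing])
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2:
        raise ValueError("degenerate superposition: points are collinear")
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = yc - rot @ xc
    moved = x @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_pairs=len(pairing))


def apply_superposition(sup: Superposition, obj: ChainModel | ComplexStructure) -> None:
    """Apply a superposition in place to every atom of a chain or complex."""
    chains = obj.chains if isinstance(obj, ComplexStructure) else [obj]
    for chain in chains:
        for res in chain:
            for atom in res.atoms:
                atom.xyz = sup.transform(atom.xyz)


# ---------------------------------------------------------------------------
# clash counting

def clash_count(model: ChainModel | ComplexStructure, cutoff: float = 2.2) -> int:
    """Count non-bonded heavy-atom pairs closer than ``cutoff``.

    Pairs within one residue are skipped (bonded), as are backbone-backbone
    pairs of sequence-adjacent residues (peptide-bond neighborhood).
    """
    chains = model.chains if isinstance(model, ComplexStructure) else [model]
    coords, meta = [], []  # meta: (chain index, residue index, is backbone)
    for ci, chain in enumerate(chains):
        for ri, res in enumerate(chain):
            for atom in res.heavy_atoms():
                coords.append(atom.xyz)
                meta.append((ci, ri, atom.name in _BACKBONE))
    if not coords:
        return 0
    tree = cKDTree(np.array(coords))
    count = 0
    for i, j in tree.query_pairs(r=cutoff, eps=0.0):
        ci, ri, bb_i = meta[i]
        cj, rj, bb_j = meta[j]
        if ci == cj and ri == rj:
            continue
        if ci == cj and abs(ri - rj) == 1 and bb_i and bb_j:
            continue
        count += 1
    return count
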