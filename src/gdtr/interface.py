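"""Geometric classification of protein-protein interface interactions.

Interface residues are those with any heavy atom within a cutoff (default
4.0 A) of the partner group.  Residue pairs across the interface are then
typed by distance rules in the spirit of the Protein Interactions
Calculator conventions:

* ionic           — opposite formally charged side-chain atoms <= 6.0 A
* hydrogen bonds  — donor-acceptor heavy atoms <= 3.5 A, sub-typed by
                    main-chain / side-chain membership (MM / MS / SS); no
                    angle term, since threaded models carry no hydrogens
* aromatic-aromatic — ring centroids within [4.5, 7.0] A (Phe/Tyr/Trp/His)
* aromatic-sulfur  — ring centroid to Cys SG / Met SD <= 5.3 A
* cation-pi        — ring centroid to Lys NZ / Arg guanidinium N <= 6.0 A
* hydrophobic      — side-chain carbon pair <= 5.0 A between apolar residues

His is treated as both potentially cationic and aromatic.  "Within X A"
means <= X; the aromatic window is inclusive on both ends.  One contact is
kept per (residue pair, type), at the minimal defining distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .imgt import NumberingCorrespondence
from .structures import ComplexStructure, Residue, three_to_one

__all__ = [
    "InteractionType",
    "ContactParams",
    "ResidueRef",
    "Contact",
    "ContactTable",
    "interface_residues",
    "classify_pair",
    "contact_table",
    "summarize_table",
    "TableSummary",
]


class InteractionType(str, Enum):
    IONIC = "IONIC"
    HBOND_SS = "HBOND_SS"
    HBOND_MS = "HBOND_MS"
    HBOND_MM = "HBOND_MM"
    AROMATIC_AROMATIC = "AROMATIC_AROMATIC"
    AROMATIC_SULFUR = "AROMATIC_SULFUR"
    CATION_PI = "CATION_PI"
    HYDROPHOBIC = "HYDROPHOBIC"


@dataclass(frozen=True)
class ContactParams:
    """Distance thresholds (A) for each interaction class."""

    ionic: float = 6.0
    hbond: float = 3.5
    aromatic_lo: float = 4.5
    aromatic_hi: float = 7.0
    aromatic_sulfur: float = 5.3
    cation_pi: float = 6.0
    hydrophobic: float = 5.0
    interface_cutoff: float = 4.0


_MAIN_CHAIN = {"N", "CA", "C", "O", "OXT"}

_NEGATIVE = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_POSITIVE = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}

_RINGS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

_SULFUR = {"CYS": ("SG",), "MET": ("SD",)}

_SC_DONORS = {
    "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",), "ASN": ("ND2",), "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "TRP": ("NE1",), "CYS": ("SG",),
}
_SC_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",), "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "CYS": ("SG",),
}

_HYDROPHOBIC_RES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}


@dataclass(frozen=True)
class ResidueRef:
    chain_id: str
    author_number: int
    insertion_code: str
    name3: str
    imgt: str | None = None
    region: str | None = None

    @property
    def one_letter(self) -> str:
        return three_to_one(self.name3)


@dataclass(frozen=True)
class Contact:
    res_a: ResidueRef
    res_b: ResidueRef
    kind: InteractionType
    distance: float | None
    partners: str = ""


@dataclass
class ContactTable:
    contacts: list[Contact]
    groups: tuple[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [(c.res_a, c.res_b, c.kind) for c in self.contacts]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (res_a, res_b, kind) contacts")

    def __len__(self) -> int:
        return len(self.contacts)

    _COLUMNS = [
        "chain_a", "region_a", "aa3_a", "aa1_a", "imgt_a", "author_a",
        "kind", "distance",
        "chain_b", "region_b", "aa3_b", "aa1_b", "imgt_b", "author_b",
    ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.contacts:
            rows.append({
                "chain_a": c.res_a.chain_id, "region_a": c.res_a.region or "",
                "aa3_a": c.res_a.name3, "aa1_a": c.res_a.one_letter,
                "imgt_a": c.res_a.imgt or "",
                "author_a": f"{c.res_a.author_number}{c.res_a.insertion_code}",
                "kind": c.kind.value,
                "distance": "" if c.distance is None else f"{c.distance:.2f}",
                "chain_b": c.res_b.chain_id, "region_b": c.res_b.region or "",
                "aa3_b": c.res_b.name3, "aa1_b": c.res_b.one_letter,
                "imgt_b": c.res_b.imgt or "",
                "author_b": f"{c.res_b.author_number}{c.res_b.insertion_code}",
            })
        return pd.DataFrame(rows, columns=self._COLUMNS)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, groups: tuple[str, str] = ("A", "B")) -> "ContactTable":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        contacts = []
        for _, row in frame.iterrows():
            def ref(side: str) -> ResidueRef:
                author = row[f"author_{side}"]
                number, icode = 0, ""
                if author:
                    if author[-1].isalpha():
                        number, icode = int(author[:-1]), author[-1]
                    else:
                        number = int(author)
                return ResidueRef(
                    chain_id=row[f"chain_{side}"], author_number=number,
                    insertion_code=icode, name3=row[f"aa3_{side}"],
                    imgt=row[f"imgt_{side}"] or None,
                    region=row[f"region_{side}"] or None,
                )
            distance = float(row["distance"]) if row["distance"] else None
            contacts.append(Contact(ref("a"), ref("b"), InteractionType(row["kind"]), distance))
        return cls(contacts=contacts, groups=groups, provenance=str(path))


# ---------------------------------------------------------------------------

def _heavy_coords(res: Residue, names: tuple[str, ...]) -> np.ndarray | None:
    xyz = [a.xyz for name in names if (a := res.atom(name)) is not None]
    if len(xyz) < len(names):
        return None
    return np.array(xyz)


def _min_distance(xa: np.ndarray, xb: np.ndarray) -> tuple[float, int, int]:
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return float(d[i, j]), int(i), int(j)


def _ring_centroid(res: Residue) -> np.ndarray | None:
    names = _RINGS.get(res.name3)
    if names is None:
        return None
    xyz = _heavy_coords(res, names)
    if xyz is None:
        warnings.warn(
            f"{res.name3} {res.author_number}: incomplete ring, aromatic types skipped"
        )
        return None
    return xyz.mean(axis=0)


def _charged_atoms(res: Residue, table: dict) -> list:
    names = table.get(res.name3)
    if not names:
        return []
    atoms = [a for n in names if (a := res.atom(n)) is not None]
    if not atoms:
        warnings.warn(
            f"{res.name3} {res.author_number}: charged-group atoms missing, ionic skipped"
        )
    return atoms


def _donors(res: Residue) -> list[tuple[str, np.ndarray, bool]]:
    out = []
    if (n := res.atom("N")) is not None and res.name3 != "PRO":
        out.append(("N", n.xyz, True))
    for name in _SC_DONORS.get(res.name3, ()):
        if (a := res.atom(name)) is not None:
            out.append((name, a.xyz, False))
    return out


def _acceptors(res: Residue) -> list[tuple[str, np.ndarray, bool]]:
    out = []
    for name in ("O", "OXT"):
        if (a := res.atom(name)) is not None:
            out.append((name, a.xyz, True))
    for name in _SC_ACCEPTORS.get(res.name3, ()):
        if (a := res.atom(name)) is not None:
            out.append((name, a.xyz, False))
    return out


def classify_pair(
    res_a: Residue,
    res_b: Residue,
    params: ContactParams = ContactParams(),
    ref_a: ResidueRef | None = None,
    ref_b: ResidueRef | None = None,
) -> list[Contact]:
    """All interaction types applicable to a residue pair, each reported
    once with its minimal defining distance."""
    ra = ref_a or ResidueRef("A", res_a.author_number, res_a.insertion_code, res_a.name3)
    rb = ref_b or ResidueRef("B", res_b.author_number, res_b.insertion_code, res_b.name3)
    contacts: list[Contact] = []

    def emit(kind: InteractionType, distance: float, partners: str) -> None:
        contacts.append(Contact(ra, rb, kind, round(distance, 3), partners))

    # ionic: opposite formal charges
    for ta, tb in ((_POSITIVE, _NEGATIVE), (_NEGATIVE, _POSITIVE)):
        aa = _charged_atoms(res_a, ta)
        ab = _charged_atoms(res_b, tb)
        if aa and ab:
            d, i, j = _min_distance(np.array([a.xyz for a in aa]), np.array([a.xyz for a in ab]))
            if d <= params.ionic:
                emit(InteractionType.IONIC, d, f"{aa[i].name}-{ab[j].name}")
                break

    # hydrogen bonds, sub-typed by chain membership
    best: dict[InteractionType, tuple[float, str]] = {}
    for donors, acceptors, flip in ((_donors(res_a), _acceptors(res_b), False),
                                    (_donors(res_b), _acceptors(res_a), True)):
        for dn, dxyz, d_main in donors:
            for an, axyz, a_main in acceptors:
                d = float(np.linalg.norm(dxyz - axyz))
                if d > params.hbond:
                    continue
                if d_main and a_main:
                    kind = InteractionType.HBOND_MM
                elif d_main or a_main:
                    kind = InteractionType.HBOND_MS
                else:
                    kind = InteractionType.HBOND_SS
                partners = f"{an}-{dn}" if flip else f"{dn}-{an}"
                if kind not in best or d < best[kind][0]:
                    best[kind] = (d, partners)
    for kind, (d, partners) in sorted(best.items(), key=lambda kv: kv[0].value):
        emit(kind, d, partners)

    # aromatic-aromatic
    ca, cb = _ring_centroid(res_a), _ring_centroid(res_b)
    if ca is not None and cb is not None:
        d = float(np.linalg.norm(ca - cb))
        if params.aromatic_lo <= d <= params.aromatic_hi:
            emit(InteractionType.AROMATIC_AROMATIC, d, "ring-ring")

    # aromatic-sulfur and cation-pi (either orientation)
    for centroid, other, rr in ((ca, res_b, False), (cb, res_a, True)):
        if centroid is None:
            continue
        s_atoms = [a for n in _SULFUR.get(other.name3, ()) if (a := other.atom(n)) is not None]
        if s_atoms:
            d, _, j = _min_distance(centroid[None, :], np.array([a.xyz for a in s_atoms]))
            if d <= params.aromatic_sulfur:
                emit(InteractionType.AROMATIC_SULFUR, d, f"ring-{s_atoms[j].name}")
        cat = [a for n in {**_POSITIVE}.get(other.name3, ()) if other.name3 != "HIS"
               and (a := other.atom(n)) is not None]
        if cat:
            d, _, j = _min_distance(centroid[None, :], np.array([a.xyz for a in cat]))
            if d <= params.cation_pi:
                emit(InteractionType.CATION_PI, d, f"ring-{cat[j].name}")

    # hydrophobic: apolar side-chain carbon pairs
    if res_a.name3 in _HYDROPHOBIC_RES and res_b.name3 in _HYDROPHOBIC_RES:
        sc_a = [a.xyz for a in res_a.heavy_atoms()
                if a.element == "C" and a.name not in _MAIN_CHAIN]
        sc_b = [a.xyz for a in res_b.heavy_atoms()
                if a.element == "C" and a.name not in _MAIN_CHAIN]
        if sc_a and sc_b:
            d, _, _ = _min_distance(np.array(sc_a), np.array(sc_b))
            if d <= params.hydrophobic:
                emit(InteractionType.HYDROPHOBIC, d, "C-C")

    # dedup: one contact per type at minimal distance
    out: dict[InteractionType, Contact] = {}
    for c in contacts:
        if c.kind not in out or c.distance < out[c.kind].distance:
            out[c.kind] = c
    return sorted(out.values(), key=lambda c: c.kind.value)


def interface_residues(
    s: ComplexStructure,
    group_a: set[str] | list[str],
    group_b: set[str] | list[str],
    cutoff: float = 4.0,
) -> tuple[list[tuple[str, Residue]], list[tuple[str, Residue]]]:
    """Residues of each group with any heavy atom within ``cutoff`` of the
    other group (the 4 A interface selection rule)."""
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    if group_a & group_b:
        raise ValueError("groups must be disjoint")

    def collect(group: set[str]):
        coords, owners = [], []
        entries = []
        for cid in s.chain_ids():
            if cid not in group:
                continue
            for res in s.chain(cid):
                idx = len(entries)
                entries.append((cid, res))
                for atom in res.heavy_atoms():
                    coords.append(atom.xyz)
                    owners.append(idx)
        return np.array(coords), owners, entries

    xa, owner_a, entries_a = collect(group_a)
    xb, owner_b, entries_b = collect(group_b)
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("a group has no heavy atoms")
    tree_a, tree_b = cKDTree(xa), cKDTree(xb)
    hits = tree_a.query_ball_tree(tree_b, r=cutoff)
    sel_a, sel_b = set(), set()
    for i, neighbors in enumerate(hits):
        if neighbors:
            sel_a.add(owner_a[i])
            for j in neighbors:
                sel_b.add(owner_b[j])
    return ([entries_a[i] for i in sorted(sel_a)], [entries_b[j] for j in sorted(sel_b)])


def _make_ref(
    chain_id: str, res: Residue, numberings: dict[str, NumberingCorrespondence] | None
) -> ResidueRef:
    imgt = region = None
    if numberings and chain_id in numberings:
        try:
            corr = numberings[chain_id]
            imgt = str(corr.to_imgt(res.author_number, res.insertion_code))
            region = corr.region(res.author_number, res.insertion_code)
        except KeyError:
            pass
    return ResidueRef(chain_id, res.author_number, res.insertion_code, res.name3,
                      imgt=imgt, region=region)


def contact_table(
    s: ComplexStructure,
    group_a: set[str] | list[str],
    group_b: set[str] | list[str],
    numberings: dict[str, NumberingCorrespondence] | None = None,
    params: ContactParams = ContactParams(),
    labels: tuple[str, str] | None = None,
) -> ContactTable:
    """Classify every interface residue pair between two chain groups and
    annotate the contacts with IMGT positions and region labels."""
    side_a, side_b = interface_residues(s, group_a, group_b, cutoff=params.interface_cutoff)
    contacts: list[Contact] = []
    for cid_a, res_a in side_a:
        ref_a = _make_ref(cid_a, res_a, numberings)
        for cid_b, res_b in side_b:
            ref_b = _make_ref(cid_b, res_b, numberings)
            contacts.extend(classify_pair(res_a, res_b, params, ref_a, ref_b))
    labels = labels or ("+".join(sorted(set(group_a))), "+".join(sorted(set(group_b))))
    return ContactTable(contacts=contacts, groups=labels,
                        provenance=f"{s.title or s.source}; cutoffs={params}")


@dataclass
class TableSummary:
    n_contacts: int
    by_type: dict[str, int]
    residues_per_group: dict[str, int]
    residues_per_chain: dict[str, int]
    residues_per_region: dict[str, int]


def summarize_table(t: ContactTable) -> TableSummary:
    """Deterministic counts: contacts per type, distinct residues per group,
    per chain and per region label."""
    by_type: dict[str, int] = {}
    res_group: dict[str, set] = {t.groups[0]: set(), t.groups[1]: set()}
    res_chain: dict[str, set] = {}
    res_region: dict[str, set] = {}
    for c in t.contacts:
        by_type[c.kind.value] = by_type.get(c.kind.value, 0) + 1
        for ref, group in ((c.res_a, t.groups[0]), (c.res_b, t.groups[1])):
            key = (ref.chain_id, ref.author_number, ref.insertion_code,
                   ref.imgt, ref.name3, ref.region)
            res_group[group].add(key)
            res_chain.setdefault(ref.chain_id, set()).add(key)
            if ref.region:
                res_region.setdefault(ref.region, set()).add(key)
    return TableSummary(
        n_contacts=len(t.contacts),
        by_type=dict(sorted(by_type.items())),
        residues_per_group={g: len(v) for g, v in res_group.items()},
        residues_per_chain={k: len(v) for k, v in sorted(res_chain.items())},
        residues_per_region={k: len(v) for k, v in sorted(res_region.items())},
    )
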