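"""Macromolecular structure data model and PDB/mmCIF input/output.

The in-memory model is deliberately small: a :class:`ComplexStructure` is an
ordered collection of protein chains, each chain an ordered list of residues
keeping the *author* numbering of the source file verbatim (insertion codes
included), each residue an ordered list of heavy (or hydrogen) atoms.  All
geometric stages of the pipeline — interface contact typing, clash counting,
superposition, interface energetics — operate on this model.

Parsing is delegated to gemmi; on read, waters and tabulated non-amino-acid
heteroatoms are dropped, alternate locations are collapsed to the highest
occupancy conformer (ties broken by altloc letter), and unknown residue codes
are kept with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ChainModel",
    "ComplexStructure",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "three_to_one",
]

#: Standard three-letter -> one-letter residue code table.
_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


def three_to_one(name3: str) -> str:
    """One-letter code for a three-letter residue name ('X' if unknown)."""
    return _THREE_TO_ONE.get(name3.upper(), "X")


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    occupancy: float = 1.0
    temp_factor: float = 0.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    name3: str
    author_number: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.author_number, self.insertion_code)

    @property
    def one_letter(self) -> str:
        return three_to_one(self.name3)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Residue({self.name3} {self.author_number}{self.insertion_code}, {len(self.atoms)} atoms)"


@dataclass
class ChainModel:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    molecule_label: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError(f"chain {self.chain_id}: duplicate (number, icode) residue keys")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def sequence(self) -> str:
        """One-letter sequence in residue (file) order."""
        return "".join(r.one_letter for r in self.residues)

    def residue_by_number(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.author_number == number and r.insertion_code == icode:
                return r
        return None


@dataclass
class ComplexStructure:
    chains: list[ChainModel] = field(default_factory=list)
    source: str = "synthetic"
    title: str = ""

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain ids in complex")

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in complex")

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c)


# ---------------------------------------------------------------------------
# reading

def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Collapse alternate locations: per atom name keep the copy with the
    highest occupancy, ties broken by altloc letter order."""
    by_name: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            order.append(atom.name)
        elif (atom.occ, _altloc_rank(prev.altloc)) > (prev.occ, _altloc_rank(atom.altloc)):
            # higher occupancy wins; on equal occupancy the earlier altloc
            # letter (already stored) wins, so only replace on strictly
            # higher occupancy.
            if atom.occ > prev.occ:
                by_name[atom.name] = atom
    return [by_name[n] for n in order]


def _altloc_rank(altloc: str) -> int:
    return -ord(altloc) if altloc else 0


def _keep_residue(res: gemmi.Residue) -> bool:
    if res.is_water():
        return False
    info = gemmi.find_tabulated_residue(res.name)
    if info is None or not info.found():
        warnings.warn(f"unknown residue code {res.name!r}; retained as-is")
        return True
    return info.is_amino_acid()


def read_structure(path: str | Path, format: str = "auto") -> ComplexStructure:
    """Read a PDB or mmCIF file into a :class:`ComplexStructure`.

    Protein residues of all chains are kept; waters and tabulated
    non-amino-acid heteroatoms are dropped; unknown residue codes are kept
    with a warning.  Alternate locations are resolved to the highest-occupancy
    conformer.  Only the first model of multi-model files is used.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureParseError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models in file")

    model = st[0]
    chains: list[ChainModel] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            if not _keep_residue(res):
                continue
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name or "X",
                    xyz=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    temp_factor=a.b_iso,
                )
                for a in _resolve_altlocs(res)
            ]
            icode = res.seqid.icode.strip()
            residues.append(
                Residue(name3=res.name, author_number=res.seqid.num,
                        insertion_code=icode, atoms=atoms)
            )
        if residues:
            chains.append(ChainModel(chain_id=ch.name, residues=residues))
    return ComplexStructure(chains=chains, source=fmt, title=st.name or path.stem)


# ---------------------------------------------------------------------------
# writing

def write_structure(s: ComplexStructure, path: str | Path, format: str = "pdb") -> Path:
    """Write a complex as a fixed-column PDB file (round-trips through
    :func:`read_structure`)."""
    if format != "pdb":
        raise ValueError(f"only PDB output is supported, not {format!r}")
    st = gemmi.Structure()
    st.name = s.title or "gdtr model"
    model = gemmi.Model("1")
    for chain in s.chains:
        if len(chain.chain_id) > 1:
            raise ValueError(
                f"chain id {chain.chain_id!r} too long for PDB format (1 character)"
            )
        gch = gemmi.Chain(chain.chain_id)
        for res in chain:
            if any(not np.all(np.isfinite(a.xyz)) for a in res.atoms):
                raise ValueError(f"non-finite coordinates in residue {res.key}")
            gres = gemmi.Residue()
            gres.name = res.name3
            gres.seqid = gemmi.SeqId(res.author_number, res.insertion_code or " ")
            gres.het_flag = "A"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.xyz)
                ga.occ = atom.occupancy
                ga.b_iso = atom.temp_factor
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path
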