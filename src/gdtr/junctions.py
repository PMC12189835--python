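"""CDR3-IMGT junction delimitation and decomposition of rearranged clones.

A productive V-(D)-J rearrangement is analyzed at the amino-acid level to
locate the conserved anchors (2nd-CYS 104 and the J-PHE/J-TRP 118 of the
F/W-G-X-G J-MOTIF), and at the nucleotide level to decompose the CDR3-IMGT
(codons 105-117) into its germline contributions: the 3'V-REGION, zero or
more D-REGION blocks, the 5'J-REGION, and untemplated/palindromic (P/N)
stretches.  Multiple D segments per junction — up to four in dromedary TRD
clones — underlie the very long CDR3 loops this pipeline targets.

P and N nucleotides are not distinguished (reported jointly as PN): telling
them apart requires germline-end palindrome tests outside this scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "RearrangedClone",
    "GermlineSegment",
    "Block",
    "JunctionAnnotation",
    "JunctionError",
    "locate_anchors",
    "extract_cdr3",
    "attribute_d_segments",
    "length_stats",
]

_NT_ALPHABET = set("ACGTN")


class JunctionError(ValueError):
    """Raised when a junction cannot be delimited or is unproductive."""


@dataclass
class RearrangedClone:
    """One rearranged cDNA clone (e.g. SC19 from spleen)."""

    name: str
    nt_seq: str
    tissue: str = "unknown"
    reading_frame: int = 0
    locus: str = "TRD"

    def __post_init__(self) -> None:
        self.nt_seq = self.nt_seq.upper()
        if not set(self.nt_seq) <= _NT_ALPHABET:
            bad = sorted(set(self.nt_seq) - _NT_ALPHABET)
            raise ValueError(f"clone {self.name}: non-nucleotide symbols {bad}")
        if self.reading_frame not in (0, 1, 2):
            raise ValueError("reading_frame must be 0, 1 or 2")

    def aa_seq(self) -> str:
        nt = self.nt_seq[self.reading_frame:]
        nt = nt[: len(nt) - len(nt) % 3]
        return str(Seq(nt).translate())


@dataclass
class GermlineSegment:
    gene_name: str
    segment_type: str
    nt_seq: str

    def __post_init__(self) -> None:
        self.nt_seq = self.nt_seq.upper()
        if self.segment_type not in ("V", "D", "J"):
            raise ValueError("segment_type must be V, D or J")
        if self.segment_type == "D" and len(self.nt_seq) > 30:
            raise ValueError(f"{self.gene_name}: D segments are short (<= 30 nt)")


@dataclass
class Block:
    """One contiguous junction block: origin is 3'V, D:<gene>, 5'J or PN;
    start/end are nucleotide offsets within the CDR3 (end exclusive)."""

    origin: str
    start: int
    end: int
    mismatch_positions: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class JunctionAnnotation:
    clone_name: str
    cdr3_nt: str
    cdr3_aa: str
    length_aa: int
    blocks: list[Block]
    d_genes_used: list[str]
    tissue: str = "unknown"

    def __post_init__(self) -> None:
        if self.length_aa != len(self.cdr3_aa):
            raise ValueError("length_aa must equal len(cdr3_aa)")
        cover = sorted((b.start, b.end) for b in self.blocks)
        pos = 0
        for s, e in cover:
            if s != pos:
                raise ValueError("blocks must tile the CDR3 exactly")
            pos = e
        if pos != len(self.cdr3_nt):
            raise ValueError("blocks must tile the CDR3 exactly")

    def block_string(self) -> str:
        """CDR3 nucleotides with the printed case convention: germline V/J
        contributions upper-case, D and PN stretches lower-case."""
        out = []
        for b in sorted(self.blocks, key=lambda b: b.start):
            nt = self.cdr3_nt[b.start : b.end]
            out.append(nt.upper() if b.origin in ("3'V", "5'J") else nt.lower())
        return "".join(out)


# ---------------------------------------------------------------------------

def locate_anchors(aa_seq: str) -> tuple[int, int]:
    """Locate the 2nd-CYS (104) and J-PHE/J-TRP (118) anchors.

    Returns 0-based indices ``(pos_104, pos_118)``.  Position 118 is the
    F/W of the first F/W-G-X-G motif downstream of a Cys at plausible
    V-FR3 distance (5-45 residues upstream of the motif); among candidate
    Cys the nearest upstream wins.
    """
    aa_seq = aa_seq.upper()
    for j in range(len(aa_seq) - 3):
        if aa_seq[j] in "FW" and aa_seq[j + 1] == "G" and aa_seq[j + 3] == "G":
            cys = [c for c in range(len(aa_seq)) if aa_seq[c] == "C" and 5 <= j - c <= 45]
            if not cys:
                continue
            if len(cys) > 1:
                warnings.warn(
                    f"multiple candidate 2nd-CYS positions {cys} upstream of J-motif "
                    f"at {j}; choosing the nearest"
                )
            return (max(cys), j)
    raise JunctionError("J-MOTIF not found")


def _translate(nt: str) -> str:
    nt = nt[: len(nt) - len(nt) % 3]
    return str(Seq(nt).translate()) if nt else ""


def _germline_v_3prime(v_ref: GermlineSegment) -> str:
    """Germline V nucleotides downstream of the 2nd-CYS codon (the part of
    the V-REGION that can extend into the CDR3).  The V reference is taken
    in reading frame 0; its 2nd-CYS is the last Cys in the translation."""
    aa = _translate(v_ref.nt_seq)
    c = aa.rfind("C")
    if c < 0:
        raise JunctionError(f"{v_ref.gene_name}: no Cys codon in V reference")
    return v_ref.nt_seq[(c + 1) * 3 :]


def _germline_j_5prime(j_ref: GermlineSegment) -> str:
    """Germline J nucleotides upstream of the J-PHE/J-TRP codon, in the
    frame in which the F/W-G-X-G motif appears."""
    for frame in range(3):
        aa = _translate(j_ref.nt_seq[frame:])
        for j in range(len(aa) - 3):
            if aa[j] in "FW" and aa[j + 1] == "G" and aa[j + 3] == "G":
                return j_ref.nt_seq[: frame + j * 3]
    raise JunctionError(f"{j_ref.gene_name}: no J-MOTIF in J reference")


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def attribute_d_segments(
    junction_nt: str,
    d_refs: list[GermlineSegment],
    min_match: int = 5,
    max_mismatch: int = 1,
) -> list[Block]:
    """Attribute stretches of a junction to germline D segments.

    Every (gene, gene offset, junction offset, window length) ungapped
    match of length >= ``min_match`` with <= ``max_mismatch`` substitutions
    is a candidate; candidates are chosen greedily (longest, then fewest
    mismatches, then leftmost in the junction, then gene name) subject to
    non-overlap, and reported left to right with PN blocks filling the
    unassigned stretches.
    """
    junction_nt = junction_nt.upper()
    n = len(junction_nt)
    candidates: list[tuple[int, int, int, str, int, list[int]]] = []
    for ref in sorted(d_refs, key=lambda r: r.gene_name):
        d = ref.nt_seq
        for j_off in range(n):
            for d_off in range(len(d)):
                max_len = min(n - j_off, len(d) - d_off)
                mism: list[int] = []
                for k in range(max_len):
                    if junction_nt[j_off + k] != d[d_off + k]:
                        mism.append(j_off + k)
                    if len(mism) > max_mismatch:
                        max_len = k  # longer windows only add mismatches
                        break
                    if k + 1 >= min_match:
                        candidates.append(
                            (-(k + 1), len(mism), j_off, ref.gene_name, d_off, list(mism))
                        )
    candidates.sort(key=lambda c: c[:5])
    chosen: list[tuple[int, int, str, list[int]]] = []  # (start, end, gene, mismatches)
    occupied = [False] * n
    for neg_len, _n_mism, j_off, gene, _d_off, mism in candidates:
        length = -neg_len
        if any(occupied[j_off : j_off + length]):
            continue
        # a match may not end (or start) on a mismatch: trimming it would
        # leave a better candidate, which the enumeration already contains
        if mism and (mism[0] == j_off or mism[-1] == j_off + length - 1):
            continue
        chosen.append((j_off, j_off + length, gene, mism))
        for i in range(j_off, j_off + length):
            occupied[i] = True
    chosen.sort()
    blocks: list[Block] = []
    pos = 0
    for start, end, gene, mism in chosen:
        if start > pos:
            blocks.append(Block("PN", pos, start))
        blocks.append(Block(f"D:{gene}", start, end, mismatch_positions=mism))
        pos = end
    if pos < n:
        blocks.append(Block("PN", pos, n))
    return blocks


def extract_cdr3(
    clone: RearrangedClone,
    v_ref: GermlineSegment,
    j_ref: GermlineSegment,
    d_refs: list[GermlineSegment] | None = None,
    min_match: int = 5,
    max_mismatch: int = 1,
) -> JunctionAnnotation:
    """Delimit the CDR3-IMGT of a clone and attribute its germline blocks.

    The CDR3 spans codons 105-117: it starts at the codon after the
    2nd-CYS and ends at the codon before J-PHE/J-TRP 118.  The leading
    germline 3'V and trailing 5'J contributions are delimited as longest
    exact matches to the references; the remainder goes through D
    attribution (all PN for a D-less locus such as TRG).
    """
    d_refs = d_refs or []
    aa = clone.aa_seq()
    c104, j118 = locate_anchors(aa)
    cdr3_aa = aa[c104 + 1 : j118]
    if "*" in cdr3_aa:
        raise JunctionError(f"clone {clone.name}: unproductive junction (internal stop)")
    nt_start = clone.reading_frame + (c104 + 1) * 3
    nt_end = clone.reading_frame + j118 * 3
    cdr3_nt = clone.nt_seq[nt_start:nt_end]

    v3 = _germline_v_3prime(v_ref)
    j5 = _germline_j_5prime(j_ref)
    n_v = _common_prefix_len(cdr3_nt, v3)
    n_j = _common_prefix_len(cdr3_nt[n_v:][::-1], j5[::-1])

    blocks: list[Block] = []
    if n_v:
        blocks.append(Block("3'V", 0, n_v))
    middle = cdr3_nt[n_v : len(cdr3_nt) - n_j]
    for b in attribute_d_segments(middle, d_refs, min_match, max_mismatch):
        blocks.append(
            Block(b.origin, b.start + n_v, b.end + n_v,
                  mismatch_positions=[m + n_v for m in b.mismatch_positions])
        )
    if n_j:
        blocks.append(Block("5'J", len(cdr3_nt) - n_j, len(cdr3_nt)))
    d_genes = [b.origin.split(":", 1)[1] for b in blocks if b.origin.startswith("D:")]
    return JunctionAnnotation(
        clone_name=clone.name,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        length_aa=len(cdr3_aa),
        blocks=blocks,
        d_genes_used=d_genes,
        tissue=clone.tissue,
    )


def length_stats(annotations: list[JunctionAnnotation], group_by: str = "tissue") -> pd.DataFrame:
    """Per-group (n, min, max, mean) summary of CDR3-IMGT lengths."""
    if not annotations:
        raise ValueError("no annotations to summarize")
    frame = pd.DataFrame(
        {
            "clone": [a.clone_name for a in annotations],
            "tissue": [a.tissue for a in annotations],
            "length_aa": [a.length_aa for a in annotations],
        }
    )
    out = (
        frame.groupby(group_by)["length_aa"]
        .agg(n="count", min="min", max="max", mean="mean")
        .reset_index()
        .sort_values(group_by)
        .reset_index(drop=True)
    )
    return out
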