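import warnings

import numpy as np
import pytest

from gdtr.junctions import GermlineSegment
from gdtr.synthetic import default_germline


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Generator retry loops legitimately emit advisory warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def germline():
    v, j, d_refs = default_germline()
    return {"V": v, "J": j, "D": d_refs}


# ---------------------------------------------------------------------------
# independent oracles

def needleman_wunsch_gotoh(a: str, b: str, matrix, gap_open: float, gap_extend: float):
    """Reference global alignment score: affine gaps costing
    gap_open + (k - 1) * gap_extend, end gaps included."""
    inf = float("inf")
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), -inf)
    Ix = np.full((n + 1, m + 1), -inf)  # gap in b (a consumed)
    Iy = np.full((n + 1, m + 1), -inf)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend,
                           Iy[i - 1, j] - gap_open)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend,
                           Ix[i, j - 1] - gap_open)
    return max(M[n, m], Ix[n, m], Iy[n, m])


def brute_force_d_blocks(junction: str, d_refs: list[GermlineSegment],
                         min_match: int, max_mismatch: int):
    """Reference D attribution: exhaustive enumeration of every
    (gene, gene offset, junction offset, length) window followed by the
    same greedy rule, written independently of the library path."""
    junction = junction.upper()
    cands = []
    for ref in d_refs:
        d = ref.nt_seq.upper()
        for length in range(min_match, len(d) + 1):
            for j_off in range(0, len(junction) - length + 1):
                for d_off in range(0, len(d) - length + 1):
                    mism = [j_off + k for k in range(length)
                            if junction[j_off + k] != d[d_off + k]]
                    if len(mism) > max_mismatch:
                        continue
                    if mism and (mism[0] == j_off or mism[-1] == j_off + length - 1):
                        continue
                    cands.append((-length, len(mism), j_off, ref.gene_name, d_off, mism))
    cands.sort(key=lambda c: c[:5])
    taken = []
    used = set()
    for neg_len, _nm, j_off, gene, _d_off, mism in cands:
        span = set(range(j_off, j_off - neg_len))
        if span & used:
            continue
        used |= span
        taken.append((j_off, j_off - neg_len, gene, mism))
    taken.sort()
    blocks = []
    pos = 0
    for s, e, gene, mism in taken:
        if s > pos:
            blocks.append(("PN", pos, s, []))
        blocks.append((f"D:{gene}", s, e, mism))
        pos = e
    if pos < len(junction):
        blocks.append(("PN", pos, len(junction), []))
    return blocks


def brute_force_interface(s, group_a, group_b, cutoff):
    """Reference interface selection by exhaustive all-pairs distances."""
    def residues(group):
        return [(cid, res) for cid in s.chain_ids() if cid in group
                for res in s.chain(cid)]

    sel_a, sel_b = set(), set()
    for cid_a, res_a in residues(group_a):
        for cid_b, res_b in residues(group_b):
            close = any(
                np.linalg.norm(x.xyz - y.xyz) <= cutoff
                for x in res_a.heavy_atoms() for y in res_b.heavy_atoms()
            )
            if close:
                sel_a.add((cid_a, res_a.key))
                sel_b.add((cid_b, res_b.key))
    return sel_a, sel_b
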