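# Methods

This note documents the models, conventions and numerical choices behind
`gdtr`, and what its synthetic fixtures do and do not establish about
real data.

## IMGT unique numbering

**V-domain.** Framework/CDR boundaries are fixed at the standard IMGT
positions: FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65, FR3 66–104,
CDR3 105–117, FR4 118–128, with anchors 1st-CYS 23, CONSERVED-TRP 41,
2nd-CYS 104 and J-PHE/J-TRP 118 (the F/W of the F/W-G-X-G J-MOTIF).
Anchor detection enumerates every (Cys, Trp, Cys, J-motif) layout
consistent with full-length FR2 (17 residues) and FR3 (39 residues) and
CDR lengths in the allowed ranges (CDR1 1–12, CDR2 0–10, CDR3 1–40),
preferring the layout with the fullest FR1 and then the shortest CDRs.
FR1 may be shorter than 26; absent FR1 positions default to 10, 9, 8, …
(the gap observed in TR V-REGIONs), overridable through `hints`.
Sequences with flanking context need a `start` hint — the assignment is
then identical to the bare domain, a tested invariant.

Short CDRs are gapped at the loop apex, alternating outward
(CDR1 removal order 33, 32, 34, 31, …; CDR2 61, 60, 62, …;
CDR3 111, 112, 110, 113, …). CDR3 loops longer than 13 residues gain
insertion positions filled alternately 111.1, 112.1, 111.2, 112.2, …,
the 111 side taking the larger share for odd counts; ordering is
111 < 111.1 < 111.2 < … < 112.2 < 112.1 < 112. A 37-residue CDR3
therefore occupies 111.1–111.12 and 112.12–112.1, which is how the very
long dromedary V-delta loops are numbered.

**G-domain.** Queries are numbered 1–92 by global alignment (BLOSUM62,
gap open 10 / extend 0.5) to a shipped reference profile; query residues
inserted after reference position *p* become *p*A, *p*B, …. Score-neutral
gap placements are canonicalized so an inserted duplicate letter follows
its base position (the insertion-after convention). Alignments covering
under 50% of the reference are rejected as "not a G-domain". The shipped
profiles (`data/g_domain_reference_synthetic.json`) are **synthetic**
constructions — 92 positions, helix annotated at 50–92 — carrying the
residue inventory the interface tables use; they are not extracted from
any deposited structure, and a user analyzing real CD1D sequences should
substitute a profile built from a real G-domain.

## Junction decomposition

The CDR3-IMGT of a clone spans the codons strictly between the 2nd-CYS
codon and the J-F/W codon. The 2nd-CYS is the nearest Cys 5–45 residues
upstream of the first downstream J-motif (first motif wins; nearest Cys
wins with a warning when several qualify). The leading 3'V and trailing
5'J contributions are the longest exact matches to the germline
references; the remainder is attributed to D segments by enumerating all
ungapped windows of length ≥ `min_match` (default 5 nt) with ≤
`max_mismatch` substitutions (default 1; both config-exposed), chosen
greedily longest-first (ties: fewer mismatches, leftmost, gene name) with
matches forbidden to start or end on a substitution. Unassigned
stretches are reported jointly as PN: separating P from N nucleotides
requires germline-end palindrome tests that are out of scope. The
defaults reflect the shortest D contribution distinguishable from chance
at junction scale; the test suite checks the greedy result against an
exhaustive enumeration oracle on junctions up to 60 nt.

## Threading, superposition, clash counting

Threading copies template backbone (N, CA, C, O) along the alignment;
identical residues keep the whole template side chain, substitutions are
truncated to CB (template CB or an ideal tetrahedral CB at 1.53 Å).
Query insertions are flagged, never rebuilt — loop modeling would be
invented geometry, so contact analysis must tolerate the flagged gaps.
Models are numbered 1..n by query position. Alignments covering < 60% of
the query are rejected. Superposition is the closed-form Kabsch SVD
solution over paired Cα atoms (≥ 3 non-collinear pairs); the tests
recover planted rotations to 1e-6 and check rigid-pretransform
invariance. Because threading copies coordinates, a model superposed on
its own template has RMSD ≈ 0 by construction; published model-vs-template
RMSD values in the 0.5–0.6 Å range reflect external energy-minimization
drift and are not reproducible by threading alone — by design. The clash
counter reports non-bonded heavy-atom pairs closer than 2.2 Å, skipping
intra-residue pairs and adjacent-residue backbone contacts; it is a
coarse model-sanity check, not a calibrated quality score.

## Interface contact typing

Interface residues have any heavy atom within 4 Å of the partner group
(config-exposed); all cross pairs of interface residues are then typed.
Thresholds: ionic ≤ 6 Å between oppositely charged side-chain atoms (His
ND1/NE2 counted potentially cationic, so His participates in both ionic
and aromatic classes); hydrogen bonds ≤ 3.5 Å donor–acceptor heavy-atom
distance with no angle term (threaded models carry no hydrogens),
sub-typed main/main, main/side, side/side; aromatic–aromatic ring
centroids within [4.5, 7.0] Å inclusive (where printed sources disagree
between 4.4 and 4.5 for the lower bound, 4.5 is adopted);
aromatic–sulfur ≤ 5.3 Å; cation–π ≤ 6 Å (Lys NZ, Arg NE/NH1/NH2);
hydrophobic ≤ 5 Å between side-chain carbons of apolar residues.
"Within X Å" means ≤ X throughout. One contact is kept per (residue
pair, type) at the minimal defining distance; missing side-chain atoms
skip the affected type with a warning, never fatally. The shipped
fixture TSVs (`data/table1a_*.tsv`, `data/table1b_*.tsv`) transcribe the
published contact tables for a dromedary V-gamma/V-delta pair and its
complex with CD1D; where the per-row type glyphs are not recoverable
from text, rows were assigned the unique type distribution consistent
with the printed per-type counts, and only those counts are asserted.

## Interface energy model

ΔG_int = E(complex) − [E(A) + E(B)] with E a sum over heavy-atom pairs
of different residues: Lennard-Jones 6-12 (per-element united-atom rmin/ε
from `data/energy_params.json`), Coulomb with distance-dependent
dielectric ε(r) = 4r over formal side-chain charges (Asp/Glu −0.5 per
carboxylate oxygen, Lys +1, Arg +1/3 per guanidinium nitrogen, His +0.25
per ring nitrogen), a −1 kcal/mol well for donor–acceptor pairs in
2.4–3.5 Å, and −0.025 kcal/mol per buried apolar carbon contact within
5 Å. Pairs beyond 12 Å contribute zero, so fully separated groups score
exactly 0; sub-1 Å overlaps are capped with a warning so output stays
finite. Because every term is pairwise, intra-group terms cancel and
ΔG_int equals the inter-group sum — asserted numerically against an
explicit unfold-and-subtract evaluation. Per-residue decomposition
assigns half of each pair term to each residue and conserves the total
to 1e-6 (validated on every report). Entropic contributions are omitted.
The contract of this module is sign, limits, decomposition consistency
and ordering behavior; its absolute kcal/mol values are not comparable
to empirical force-field suites and are never asserted against published
numbers.

## Synthetic data and what the tests show

Generators draw from independent named streams (`default_rng([crc32(name),
seed])`), so adding a generator never shifts another's output and equal
seeds reproduce byte-identical artifacts.

* **Rearrangements** are 3'V + alternating PN/D + 5'J, in frame, stop-free,
  with the first J-motif at the planted position. PN stretches are built
  base-by-base under the constraint that no D-match window (≥ min_match,
  ≤ max_mismatch) lies outside the planted blocks, so the recorded
  decomposition is provably the unique greedy parse; point mutations (at
  the configured rate) are confined to D-block interiors, emulating
  substitution-bearing D matches in hypermutated repertoires. The
  default study conditions mirror the analyzed repertoire: TRD-like
  locus with six D references, 0–6 nt PN stretches, up to four D
  segments per junction, CDR3 lengths steerable to the observed 13–37
  residue spleen range.
* **Domain sequences** plant the four anchors around random CDR loops
  (letters C/F/W excluded from loop pools so anchors stay unambiguous).
  The fixture V-domains are fixed sequences with CDR-IMGT lengths
  [6.8.15] and [7.3.37] and the tabulated interface residues planted at
  their IMGT positions; the V-delta fixture has a 25-residue FR1
  (position 10 absent), which reproduces the published IMGT→PDB
  correspondences (e.g. 109→96, 111.7→105) on a model chain numbered
  1..n.
* **Geometry fixtures** build each residue pair in an ideal local frame
  with the defining atom/centroid at exactly the requested distance and
  every other atom strictly farther from the partner, then apply one
  rigid scatter — so threshold sweeps flip exactly at the cutoffs.
  Planted complex fixtures space pairs 30 Å apart with decoy chains
  ≥ 50 Å away; their defining distances sit mid-window (some above the
  4 Å interface default), so planted-recovery tests pass
  `interface_cutoff=8.0` explicitly, as recorded in each truth record.

Passing on these fixtures establishes the geometric and combinatorial
correctness of the classifiers and decomposition, not performance on
real structures: real interfaces have correlated geometry, missing
atoms, and alternate conformers that the generators only partially
emulate (altloc handling is tested through hand-written PDB fixtures
instead).

## Problem sizes

The shipped analyses are desk-scale by choice: 100 generated clones for
junction-recovery rates, a 22-clone spleen-like repertoire spanning CDR3
lengths 13–37, 50 random planted complexes for the contact-table oracle,
and single-chain superpositions of ~140 residues. All stages are exact
or deterministic at these sizes; nothing is subsampled from larger data.

## Known limitations

* Anchor detection assumes full-length FR2/FR3; V-domains with framework
  indels need explicit hints.
* D attribution allows substitutions but no indels within a D match.
* The aromatic classes use centroid distances only (no ring-plane angle
  criterion), and hydrogen bonds have no angular term.
* The energy model's desolvation term is a contact count, not a
  surface-area model; charged termini are not modeled.
* mmCIF is read but only PDB is written; chain identifiers are limited
  to one character on output.
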