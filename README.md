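# gdtr — γδ T cell receptor / CD1D structural immunoinformatics

`gdtr` is a tested, reusable pipeline for analyzing gamma–delta T cell
receptor (TRG_TRD) complexes with the lipid-presenting molecule CD1D and
its light chain B2M, built around the dromedary (*Camelus dromedarius*)
system, whose TRD chains carry exceptionally long third
complementarity-determining regions (CDR3) assembled from multiple TRDD
segments.

It implements five connected stages:

1. **IMGT unique numbering** (`gdtr.imgt`) — assigns the standardized
   V-domain positions 1–128 (anchors 1st-CYS 23, CONSERVED-TRP 41,
   2nd-CYS 104, J-PHE/J-TRP 118; CDR1 27–38, CDR2 56–65, CDR3 105–117)
   with the CDR3 insertion scheme 111.1, 111.2, … / …, 112.2, 112.1 for
   loops longer than 13 residues, and the G-domain scheme 1–92 with
   letter insertions (e.g. 72A) for the CD1D antigen-platform domains.
   IMGT positions are mapped bijectively to author (PDB) numbering.
2. **Junction analysis** (`gdtr.junctions`) — delimits the CDR3-IMGT of
   rearranged V–(D)–J cDNA clones (codons 105→117 between the 2nd-CYS
   and the F/W-G-X-G J-MOTIF) and decomposes it into 3'V-REGION, D
   blocks (greedy longest-match attribution with bounded substitutions),
   5'J-REGION and untemplated P/N stretches, plus per-tissue CDR3 length
   statistics.
3. **Template threading** (`gdtr.modeling`) — global alignment
   (BLOSUM62, gap open 10 / extend 0.5), backbone threading onto a
   template chain with side chains kept when identical and truncated to
   CB otherwise, Kabsch least-squares superposition with Cα RMSD, and a
   steric clash counter.
4. **Interface contact typing** (`gdtr.interface`) — selects interface
   residues (heavy atoms within 4 Å across the interface) and classifies
   residue pairs into ionic (≤ 6 Å), side-/main-chain hydrogen bonds
   (≤ 3.5 Å), aromatic–aromatic (4.5–7 Å centroid), aromatic–sulfur
   (≤ 5.3 Å), cation–π (≤ 6 Å) and hydrophobic (≤ 5 Å) contacts, emitting
   TSV contact tables keyed by IMGT position and FR/CDR region.
5. **Interface energetics** (`gdtr.energy`) — an unfold-and-subtract
   interaction energy
   ΔG_int = E(AB) − [E(A) + E(B)] over pairwise Lennard-Jones, Coulomb
   (ε(r) = 4r), hydrogen-bond and apolar-desolvation terms, with
   per-term and per-residue decomposition. More negative means stronger
   binding. This is a transparent scoring model for ordering and
   decomposition, not a calibrated force field.

A synthetic-data module (`gdtr.synthetic`) generates every input with a
full ground-truth record: rearranged clones with planted segment
composition, V-/G-domain sequences with planted anchors, and coordinate
fixtures with residue pairs planted at controlled geometries for every
interaction class.

## Worked example

Number the two shipped fixture V-domains (synthetic stand-ins for a
hypermutated V-gamma and a very-long-CDR3 V-delta):

```python
>>> from gdtr.imgt import assign_v_numbering
>>> from gdtr.synthetic import rts88_like_v_gamma, sc19_like_v_delta
>>> assign_v_numbering(rts88_like_v_gamma()).cdr_lengths
(6, 8, 15)
>>> n = assign_v_numbering(sc19_like_v_delta())
>>> n.cdr_lengths
(7, 3, 37)
>>> [str(p) for p in n.region_positions("CDR3")][:10]
['105', '106', '107', '108', '109', '110', '111', '111.1', '111.2', '111.3']
```

The `[6.8.15]` / `[7.3.37]` triples are the CDR1/CDR2/CDR3 lengths in
IMGT bracket notation; the 37-residue CDR3 occupies insertion positions
111.1–111.12 and 112.12–112.1.

Decompose a generated rearranged clone and type a planted interface:

```bash
$ gdtr junction --clones clones.fasta --germline germ.fasta --out junctions.tsv
$ head -2 junctions.tsv | cut -f1,3,5
clone   length_aa  d_genes
SYN0    19         TRDD1,TRDD2
$ gdtr contacts --in toy.pdb --a G --b D --out contacts.tsv --interface-cutoff 8
2 contacts: {'HBOND_SS': 1, 'IONIC': 1}
$ gdtr energy --in toy.pdb --a G --b D --out report.json
dG_interaction = -3.625 kcal/mol
```

The junction line reads: a 19-residue CDR3 assembled from two D
segments; in the TSV block string, germline V/J nucleotides are
upper-case and D/PN stretches lower-case. The contact table found the
two planted interactions (one salt bridge, one side-chain hydrogen
bond), and the interface energy is negative, i.e. favorable.

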