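{
  "_comment": "Public sequence accessions for the real dromedary clones and chains this pipeline's fixtures emulate. Sequences are NOT shipped; download them to run the accession-gated analyses. The clone-to-accession pairing for TRD follows list order in the source records and is an assumption recorded here.",
  "TRG": {
    "RTS88": {"protein": "AFD98894.1", "nucleotide": "JF755952.1"},
    "5R1S169": {"protein": "AFD98918.1", "nucleotide": "JF792640.1",
                "naming_variants_seen": ["5R1S1S9", "5R1S169", "5R1S69"]}
  },
  "TRD": {
    "SC19": {"protein": "CAX52224.1", "nucleotide": "FN252371.1"},
    "SC54": {"protein": "CAX52229.1", "nucleotide": "FN252376.1"},
    "SC44": {"protein": "CAX52219.81", "nucleotide": "FN252345",
             "note": "protein accession recorded verbatim; '.81' is a probable typographic variant of a standard version suffix and is not silently corrected"}
  },
  "CD1D": {"protein": "XP_031291871.1"},
  "B2M": {"protein": "XP_031309022.1"},
  "template_structure": {"pdb": "4LHU"}
}
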