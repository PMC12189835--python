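{
 "_comment": "Synthetic G-domain reference profiles for the antigen-platform domains of an MH1-like (CD1D-type) molecule: 92 numbered positions, helix spanning positions 50-92, strand otherwise. These are constructed reference sequences (not extracted from any deposited structure) carrying the residue inventory the interface tables use (G-ALPHA1-LIKE D43/F55/E61/N62/H65; G-ALPHA2-LIKE F55/E65/W69).",
 "G-ALPHA1-LIKE": {
  "sequence": "DHANNDLGRIRSMPRNPLRMDMTYMSSKVAHYGLYANVAPSYDIMSENSNLIGNFYLREVENPNHKSDLSGVSKISLKNNVMTYPDHSSMKP",
  "positions": [
   "1",
   "2",
   "3",
   "4",
   "5",
   "6",
   "7",
   "8",
   "9",
   "10",
   "11",
   "12",
   "13",
   "14",
   "15",
   "16",
   "17",
   "18",
   "19",
   "20",
   "21",
   "22",
   "23",
   "24",
   "25",
   "26",
   "27",
   "28",
   "29",
   "30",
   "31",
   "32",
   "33",
   "34",
   "35",
   "36",
   "37",
   "38",
   "39",
   "40",
   "41",
   "42",
   "43",
   "44",
   "45",
   "46",
   "47",
   "48",
   "49",
   "50",
   "51",
   "52",
   "53",
   "54",
   "55",
   "56",
   "57",
   "58",
   "59",
   "60",
   "61",
   "62",
   "63",
   "64",
   "65",
   "66",
   "67",
   "68",
   "69",
   "70",
   "71",
   "72",
   "73",
   "74",
   "75",
   "76",
   "77",
   "78",
   "79",
   "80",
   "81",
   "82",
   "83",
   "84",
   "85",
   "86",
   "87",
   "88",
   "89",
   "90",
   "91",
   "92"
  ],
  "helix": [
   50,
   92
  ]
 },
 "G-ALPHA2-LIKE": {
  "sequence": "PDQIYEGAHAHRMITRLYNSYDYHTYASEGMGRMYLQARYVNTSRNKIDDSEDPFDYIPTDSMPEIVTWNVGYSVHEQIHYHDNTPMDDMLQ",
  "positions": [
   "1",
   "2",
   "3",
   "4",
   "5",
   "6",
   "7",
   "8",
   "9",
   "10",
   "11",
   "12",
   "13",
   "14",
   "15",
   "16",
   "17",
   "18",
   "19",
   "20",
   "21",
   "22",
   "23",
   "24",
   "25",
   "26",
   "27",
   "28",
   "29",
   "30",
   "31",
   "32",
   "33",
   "34",
   "35",
   "36",
   "37",
   "38",
   "39",
   "40",
   "41",
   "42",
   "43",
   "44",
   "45",
   "46",
   "47",
   "48",
   "49",
   "50",
   "51",
   "52",
   "53",
   "54",
   "55",
   "56",
   "57",
   "58",
   "59",
   "60",
   "61",
   "62",
   "63",
   "64",
   "65",
   "66",
   "67",
   "68",
   "69",
   "70",
   "71",
   "72",
   "73",
   "74",
   "75",
   "76",
   "77",
   "78",
   "79",
   "80",
   "81",
   "82",
   "83",
   "84",
   "85",
   "86",
   "87",
   "88",
   "89",
   "90",
   "91",
   "92"
  ],
  "helix": [
   50,
   92
  ]
 }
}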