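{
  "scb_F": {
    "role": "receptor",
    "context": "YFHFPSKER",
    "motif_length": 4,
    "rules": [
      {"kind": "full"},
      {"kind": "full"},
      {"kind": "full"},
      {"kind": "full"},
      {"kind": "top2"},
      {"kind": "single", "codon": "AGC"},
      {"kind": "single", "codon": "AAG"},
      {"kind": "single", "codon": "GAG"},
      {"kind": "single", "codon": "CGG"}
    ]
  },
  "scb_R": {
    "role": "synthase",
    "context": "ET{ILV}RQSG",
    "motif_length": 5,
    "rules": [
      {"kind": "full"},
      {"kind": "top2"},
      {"kind": "residue_set", "residues": "ILV", "min_freq": 0.05},
      {"kind": "single", "codon": "CGC"},
      {"kind": "single", "codon": "CAG"},
      {"kind": "single", "codon": "AGC"},
      {"kind": "single", "codon": "GGC"}
    ]
  }
}
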