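{
  "version": "1.0",
  "comment": "Monoisotopic mass constants (Da). Residue masses are for amino acid residues in a peptide chain (free amino acid minus water).",
  "proton": 1.0072765,
  "water": 18.0105646,
  "residues": {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313
  },
  "monosaccharides": {
    "Hex": 162.052824,
    "HexNAc": 203.079373,
    "dHex": 146.057909,
    "NeuAc": 291.095417
  },
  "modifications": {
    "TMT6": 229.162932,
    "Carbamidomethyl": 57.021464,
    "Oxidation": 15.994915,
    "Acetyl": 42.010565,
    "Deamidation": 0.984016
  },
  "tmt6_reporters": {
    "126": 126.127726,
    "127": 127.131081,
    "128": 128.134436,
    "129": 129.137790,
    "130": 130.141145,
    "131": 131.138180
  },
  "oxonium": {
    "HexNAc": 204.086649,
    "HexNAc-2H2O": 168.065520,
    "HexNAc-CH6O3": 138.054955
  }
}
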