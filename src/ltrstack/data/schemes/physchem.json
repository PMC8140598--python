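{
  "name": "PhysChem",
  "comment": "Dinucleotide physicochemical profile tables, kcal/mol per bp step. hydrogen_bonding: mean Watson-Crick pairing energy of the two positions (A:T pair -7.00, G:C pair -16.79). stacking: base-stacking interaction energies of the 16 dinucleotide steps. solvation: mean nucleobase hydration free energy of the two positions (A -13.6, C -19.1, G -21.8, T -10.4).",
  "hydrogen_bonding": {
    "AA": -7.0, "AT": -7.0, "TA": -7.0, "TT": -7.0,
    "AC": -11.895, "CA": -11.895, "AG": -11.895, "GA": -11.895,
    "TC": -11.895, "CT": -11.895, "TG": -11.895, "GT": -11.895,
    "CC": -16.79, "CG": -16.79, "GC": -16.79, "GG": -16.79
  },
  "stacking": {
    "AA": -5.37, "AC": -10.51, "AG": -6.78, "AT": -6.57,
    "CA": -6.57, "CC": -8.26, "CG": -9.69, "CT": -6.78,
    "GA": -9.81, "GC": -14.59, "GG": -8.26, "GT": -10.51,
    "TA": -3.82, "TC": -9.81, "TG": -6.57, "TT": -5.37
  },
  "solvation": {
    "AA": -13.6, "AC": -16.35, "AG": -17.7, "AT": -12.0,
    "CA": -16.35, "CC": -19.1, "CG": -20.45, "CT": -14.75,
    "GA": -17.7, "GC": -20.45, "GG": -21.8, "GT": -16.1,
    "TA": -12.0, "TC": -14.75, "TG": -16.1, "TT": -10.4
  }
}
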