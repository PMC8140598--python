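{
  "name": "Enthalpy",
  "arity": 2,
  "neutral": 0.0,
  "comment": "Nearest-neighbor duplex formation enthalpy, kcal/mol per dinucleotide stack.",
  "table": {
    "AA": -7.9, "AC": -8.4, "AG": -7.8, "AT": -7.2,
    "CA": -8.5, "CC": -8.0, "CG": -10.6, "CT": -7.8,
    "GA": -8.2, "GC": -9.8, "GG": -8.0, "GT": -8.4,
    "TA": -7.2, "TC": -8.2, "TG": -8.5, "TT": -7.9
  }
}
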