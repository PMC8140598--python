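{
  "name": "Complementary",
  "arity": 1,
  "neutral": 0.0,
  "comment": "Injective integer map in which Watson-Crick partners are negatives of each other.",
  "table": {"A": 2.0, "T": -2.0, "C": 1.0, "G": -1.0}
}
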