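{
  "name": "Galois4",
  "arity": 1,
  "neutral": 0.0,
  "comment": "GF(4) field-element indexing of the four nucleotides.",
  "table": {"A": 0.0, "C": 1.0, "G": 2.0, "T": 3.0}
}
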