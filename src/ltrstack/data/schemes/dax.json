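{
  "name": "DAX",
  "arity": 1,
  "neutral": 0.0,
  "comment": "Integer DAX digit assignment; pyrimidines low, purines high.",
  "table": {"C": 0.0, "T": 1.0, "A": 2.0, "G": 3.0}
}
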