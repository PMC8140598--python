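{
  "name": "EIIP",
  "arity": 1,
  "neutral": 0.0,
  "comment": "Electron-ion interaction pseudopotential of each nucleotide (Rydberg).",
  "table": {"A": 0.126, "C": 0.134, "G": 0.0806, "T": 0.1335}
}
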