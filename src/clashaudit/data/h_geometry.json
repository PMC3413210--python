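{
 "angles": {
  "amine": 109.4712206,
  "hydroxyl": 108.5,
  "sp2": 120.0,
  "sp3": 109.4712206,
  "sulfhydryl": 96.0,
  "water": 104.52
 },
 "bond_lengths": {
  "C": 1.09,
  "N": 1.01,
  "O": 0.96,
  "S": 1.34
 }
}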