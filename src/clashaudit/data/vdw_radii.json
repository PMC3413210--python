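{
 "bondi": {
  "B": 1.92,
  "CA": 2.31,
  "CD": 1.58,
  "CO": 2.0,
  "CU": 1.4,
  "FE": 2.0,
  "HG": 1.55,
  "K": 2.75,
  "MG": 1.73,
  "MN": 2.05,
  "NA": 2.27,
  "NI": 1.63,
  "P": 1.8,
  "SE": 1.9,
  "ZN": 1.39
 },
 "primary": {
  "BR": 1.87,
  "C": 1.77,
  "CL": 1.76,
  "F": 1.46,
  "H": 1.1,
  "I": 2.03,
  "N": 1.64,
  "O": 1.58,
  "S": 1.81
 },
 "richardson": {
  "C": 1.7,
  "H_OTHER": 1.17,
  "H_POLAR": 1.0,
  "N": 1.55,
  "O": 1.4,
  "P": 1.8,
  "S": 1.8
 }
}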