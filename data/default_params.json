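{
  "time_unit": "min",
  "R0": 0.07,
  "EG0": 0.0015,
  "SP": 0.04861111111111111,
  "sigma0": 0.136,
  "alpha": 64.0,
  "k": 0.3,
  "d0": 0.0001,
  "r1": 1.65e-05,
  "r2": 5e-07,
  "Sbeta": 3.4
}
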