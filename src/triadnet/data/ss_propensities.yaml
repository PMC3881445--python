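# Chou-Fasman style conformational propensities used by the internal
# deterministic secondary-structure predictor (helix P_a, strand P_b).
# version: 1
helix:
  A: 1.42
  R: 0.98
  N: 0.67
  D: 1.01
  C: 0.70
  E: 1.51
  Q: 1.11
  G: 0.57
  H: 1.00
  I: 1.08
  L: 1.21
  K: 1.16
  M: 1.45
  F: 1.13
  P: 0.57
  S: 0.77
  T: 0.83
  W: 1.08
  Y: 0.69
  V: 1.06
strand:
  A: 0.83
  R: 0.93
  N: 0.89
  D: 0.54
  C: 1.19
  E: 0.37
  Q: 1.10
  G: 0.75
  H: 0.87
  I: 1.60
  L: 1.30
  K: 0.74
  M: 1.05
  F: 1.38
  P: 0.55
  S: 0.75
  T: 1.19
  W: 1.37
  Y: 1.47
  V: 1.70
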