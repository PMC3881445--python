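# Canonical amino-acid property groupings used by the CTD
# (composition/transition/distribution) encoder. Each grouping is an
# ordered, disjoint partition of the 20 canonical residues.
# version: 1
hydrophobicity:
  polar: RKEDQN
  neutral: GASTPHY
  hydrophobic: CLVIMFW
normalized_vdw_volume:
  small: GASTPDC
  medium: NVEQIL
  large: MHKFRYW
polarity:
  low: LIFWCMVY
  medium: PATGS
  high: HQRKNED
polarizability:
  low: GASDT
  medium: CPNVEQIL
  high: KMHFRYW
# Two-class accessibility: buried is the classic buried class; the
# exposed class absorbs the intermediate residues.
solvent_accessibility:
  buried: ALFCGIVW
  exposed: RKQENDMPSTHY
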