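# 5PCP-InsP5 (methylene-bisphosphonate analogue of 5PP-InsP5) chemical model,
# 31P NMR, I = 0.15 M, T = 22 C.  Cumulative log_beta, same conventions as
# insp8.model.
ligand: 5PCP-InsP5
base_charge: -13
medium: I = 0.15 M; T = 22 C

[species]
# id     n_h n_k n_mg log_beta conformer   charge
L        0   0   0    0.0      unspecified -13
HL       1   0   0    11.48    unspecified -12
H2L      2   0   0    22.42    unspecified -11
H3L      3   0   0    32.26    unspecified -10
H4L      4   0   0    40.94    unspecified -9
H5L      5   0   0    47.67    unspecified -8
H6L      6   0   0    51.93    unspecified -7
H7L      7   0   0    55.64    unspecified -6
K5HL     1   5   0    18.05    unspecified -7
K4H2L    2   4   0    27.03    unspecified -7
K4H3L    3   4   0    36.76    unspecified -6
K3H4L    4   3   0    44.88    unspecified -6
K2H5L    5   2   0    50.46    unspecified -6
MgK4HL   1   4   1    23.12    unspecified -6
MgK3H2L  2   3   1    32.17    unspecified -6
MgK3H3L  3   3   1    41.05    unspecified -5
MgK2H4L  4   2   1    47.90    unspecified -5
MgKH5L   5   1   1    52.93    unspecified -5
MgH6L    6   0   1    56.64    unspecified -5
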