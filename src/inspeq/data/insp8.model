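# InsP8 (1,5(PP)2-InsP4) chemical model, 31P NMR, I = 0.15 M, T = 22 C.
# log_beta are cumulative constants referenced to L^14- + free H+/K+/Mg2+;
# metal-complex values are the stepwise formation constants added onto the
# cumulative protonation constant of the parent H_nL state.
ligand: InsP8
base_charge: -14
medium: I = 0.15 M; T = 22 C

[species]
# id     n_h n_k n_mg log_beta conformer   charge
L        0   0   0    0.0      unspecified -14
HL       1   0   0    11.21    unspecified -13
H2L      2   0   0    22.78    unspecified -12
H3L      3   0   0    34.22    unspecified -11
H4L      4   0   0    43.96    unspecified -10
H5L      5   0   0    52.58    unspecified -9
H6L      6   0   0    59.41    unspecified -8
H7L      7   0   0    64.91    unspecified -7
H8L      8   0   0    68.79    unspecified -6
K5HL     1   5   0    23.68    unspecified -8
K4H2L    2   4   0    32.54    unspecified -8
K3H4L    4   3   0    49.406   unspecified -7
K2H5L    5   2   0    56.40    unspecified -7
KH6L     6   1   0    61.99    unspecified -7
KH7L     7   1   0    66.99    unspecified -6
MgK4L    0   4   1    22.4     unspecified -8
MgK4HL   1   4   1    32.81    unspecified -7
MgK3H2L  2   3   1    40.88    axial       -7
MgK3H3L  3   3   1    49.22    equatorial  -6
MgK2H4L  4   2   1    55.56    unspecified -6
MgKH5L   5   1   1    61.68    unspecified -6
MgKH6L   6   1   1    66.71    unspecified -5
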