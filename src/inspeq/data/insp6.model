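# InsP6 (phytate) chemical model, potentiometry, I = 0.15 M, T = 37 C.
# Cumulative log_beta, same conventions as insp8.model.
ligand: InsP6
base_charge: -12
medium: I = 0.15 M; T = 37 C (potentiometry)

[species]
# id     n_h n_k n_mg log_beta conformer   charge
L        0   0   0    0.0      unspecified -12
HL       1   0   0    10.8     unspecified -11
H2L      2   0   0    21.3     unspecified -10
H3L      3   0   0    31.63    unspecified -9
H4L      4   0   0    40.42    unspecified -8
H5L      5   0   0    47.32    unspecified -7
H6L      6   0   0    53.04    unspecified -6
H7L      7   0   0    56.14    unspecified -5
K4H3L    3   4   0    37.05    unspecified -5
K3H4L    4   3   0    43.78    unspecified -5
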