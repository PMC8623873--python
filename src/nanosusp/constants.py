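"""Physical constants used throughout the package (SI unless noted)."""

K_BOLTZMANN = 1.380649e-23   # J/K
N_AVOGADRO = 6.02214076e23   # 1/mol
R_GAS = K_BOLTZMANN * N_AVOGADRO  # J/(mol K)
G_STANDARD = 9.80665         # m/s^2, standard gravity (exact)

# unit helpers
GPA_TO_KG_MM2 = 1e9 / (G_STANDARD * 1e6)  # GPa -> kgf/mm^2
KWH_PER_TON_TO_KJ_PER_KG = 3.6            # 1 kWh/ton = 3.6 kJ/kg
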