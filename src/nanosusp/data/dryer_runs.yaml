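# Spray-dryer factorial sensitivity runs (verbatim operating table).
runs:
  run1: {F_air_kg_h: 2500.0, T_air_C: 116.0, Dn_mm: 0.007, P_air_bar: 6.0}
  run2: {F_air_kg_h: 2500.0, T_air_C: 116.0, Dn_mm: 0.007, P_air_bar: 4.5}
  run3: {F_air_kg_h: 1500.0, T_air_C: 145.0, Dn_mm: 0.007, P_air_bar: 4.5}
  run4: {F_air_kg_h: 2500.0, T_air_C: 116.0, Dn_mm: 0.03,  P_air_bar: 4.5}
  run5: {F_air_kg_h: 1500.0, T_air_C: 116.0, Dn_mm: 0.007, P_air_bar: 4.5}
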