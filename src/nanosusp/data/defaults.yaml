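# Provenance-annotated defaults for every physical constant the source
# tables do not print.  All values are configurable; none is hard-coded in
# the library.
solid:
  T_m_K: 353.15
  # provenance: printed melting point of fenofibrate, 80 degC.
  dH_m_J_mol: 33100.0
  # provenance: estimate from DSC literature, ~91.8 J/g x 360.83 g/mol.
  dCp_J_mol_K: 110.0
  # provenance: estimate; typical solid-liquid heat-capacity difference for
  # a mid-size organic crystal; not printed in the source.

nanoparticle:
  Vm_cm3_mol: 306.0
  # provenance: fenofibrate molar volume, Mw 360.83 g/mol over crystal
  # density ~1.18 g/cm3.
  S0_mol_L: 2.2e-6
  # provenance: estimate; aqueous solubility of fenofibrate at 25 degC,
  # ~0.8 mg/L (literature range 0.25-0.8 mg/L).
  radius_is_half_diameter: true
  # provenance: r in the curvature terms is taken as the particle radius
  # (the source does not state radius vs diameter).

stabilizer:
  rho_bulk_kg_m3: 1300.0
  # provenance: estimate; HPMC true density ~1.3 g/cm3.
  Mw_kg_mol: 13.0
  # provenance: estimate; Pharmacoat 603 number-average molar mass.
  Delta_layer_m: 5.0e-10
  # provenance: estimate; inter-layer molecular distance of order one
  # polymer-segment diameter (the source cites external work, value unprinted).

solubility:
  a_loading: 1.0e-4
  # provenance: estimate; initial solid API mole-fraction loading of the
  # suspension before equilibration (>> x1 so the dilute-solid regime holds).
  solvent_x_hpmc: 1.0e-5
  # provenance: ~1 wt% Pharmacoat 603 in water converted to mole fraction;
  # consistent with the stated x_HPMC < 0.01.

dryer:
  Cp_gas_dry_J_kg_K: 1006.0    # dry air
  Cp_w_vapor_J_kg_K: 1860.0    # water vapor
  Cp_w_liquid_J_kg_K: 4186.0   # liquid water
  Cp_s_dry_J_kg_K: 1200.0      # organic solids
  dHv0_J_kg: 2.501e+6          # latent heat of water at 0 degC reference
  Q_loss_W: 0.0
  Xw_crit: 0.10
  # provenance: estimate; critical wet-basis moisture content (named but
  # never quantified in the source).
  F_shape: 0.5
  k_droplet: 1.0
  # provenance: calibration input; initial droplet diameter per nozzle
  # orifice diameter (no atomization correlation is printed).
  F_s_dry_kg_h: 5.0
  X_in: 9.0
  # provenance: estimate; 10 wt% solids suspension feed on a dry basis.
  T_feed_C: 25.0
  rho_s_kg_m3: 1180.0          # fenofibrate crystal density
  rho_l_kg_m3: 998.0           # water at ambient

elastic:
  shear_hardness_coeff: 0.1475
  # provenance: reverse-engineered from the published hardness column
  # (0.1475 x G reproduces 0.901/0.465/0.683 GPa for the Voigt/Reuss/Hill
  # shear moduli).
  bwi_coeffs: [5.0e-6, -0.003, 9.6937]
  # provenance: Gent et al. quadratic linking BWI0 to Vickers hardness in
  # kg/mm^2 (the typeset "50 - 6 VH^2" is a misprint).
  correction_factors: [1.0, 1.0, 1.0, 1.0, 1.0]
  # provenance: the five BWI correction factors are not given numerically.

table3:
  # Published polycrystalline moduli of fenofibrate (inputs for the
  # averaging chain when no stiffness matrix is supplied).
  K_V_GPa: 10.45
  K_R_GPa: 8.43
  G_V_GPa: 6.11
  G_R_GPa: 3.15
  E_V_GPa: 15.34
  E_R_GPa: 8.404
  nu_V: 0.2554
  nu_R: 0.363
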