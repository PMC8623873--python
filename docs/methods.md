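# Methods

This note records the models implemented in `nanosusp`, the assumptions
behind them, the provenance of default parameters, and the numerical
choices that matter.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Elastic mechanics

A `StiffnessTensor` holds the 6×6 Voigt-notation stiffness C (GPa) and its
inverse compliance S; construction enforces symmetry to 1e-9 GPa and
mechanical stability (all eigenvalues of C strictly positive).  Computing
C from atomistics is out of scope — it is an input, typically from DFT or
force-field lattice optimization.

* **Voigt/Reuss/Hill.**  Voigt moduli are stiffness contractions (uniform
  strain, upper bound), Reuss moduli compliance contractions (uniform
  stress, lower bound), Hill the arithmetic mean — so K_R ≤ K_H ≤ K_V and
  G_R ≤ G_H ≤ G_V hold on every stable tensor, which the suite verifies
  on 1000 random SPD tensors.
* **Two Hill conventions for E and ν.**  "Closed" applies the isotropic
  relations to (K_H, G_H); "arithmetic" averages the Voigt and Reuss E
  and ν directly.  Tensor-analysis tools in circulation disagree on this
  point, and for a strongly anisotropic crystal the two differ visibly
  (11.94 vs 11.87 GPa for the shipped fenofibrate moduli), so reports
  carry both, labelled.
* **Directional properties.**  E(**n**) = 1/(n_i n_j n_k n_l S_ijkl) and
  LC(**n**) = n_i n_j S_ijkk from the full 4th-rank compliance (Voigt
  factors 1/2, 1/4); ν and G extrema scan the transverse angle in 360
  steps by default (configurable).  A tensor-rotation oracle checks the
  contraction on random tensors.
* **Hardness.**  The Mazhnik–Oganov correlation H = 0.096 χ(ν) E with
  χ(ν) = (1 − 8.5ν + 19.5ν²)/(1 − 7.5ν + 12.2ν² + 19.6ν³); it is valid
  for non-auxetic solids (0 ≤ ν < 0.5).  The alternative
  `shear_empirical` model H = 0.1475 G uses a coefficient
  reverse-engineered from a published hardness column (0.1475 × G
  reproduces 0.901/0.465/0.683 GPa for G = 6.11/3.15/4.63); it is an
  empirical proportionality, not a theory.
* **Fracture toughness.**  Mazhnik–Oganov form
  K_IC = α₀^(−1/2) V₀^(1/6) (ζ(ν) E)^(3/2), α₀ = 8840 GPa,
  ζ(ν) = (1 − 13.7ν + 48.6ν²)/(1 − 15.2ν + 70.2ν² − 81.5ν³), with V₀ the
  molecular volume (no default — it must be supplied).  For the shipped
  fenofibrate state the model gives ≈ 0.04 MPa·m^½, pinned as a
  regression value only; published tabulations of this quantity for soft
  organics are unit-ambiguous, so it is treated qualitatively.
* **Bond Work Index.**  BWI₀ = 5·10⁻⁶ VH² − 0.003 VH + 9.6937 (Gent et
  al. quadratic; VH in kg/mm², GPa→kg/mm² via g = 9.80665 exactly), then
  BWI = BWI₀ ∏ F_i with five multiplicative correction factors (open
  circuit, dry milling, mill diameter, inlet size, reduction ratio), all
  defaulting to 1 because no values are published for this system.

## Wet media milling

Rittinger's law E = C_R(1/d_p − 1/d_f) (d₈₀ sizes in µm, E in kWh/ton and
kJ/kg; 1 kWh/ton = 3.6 kJ/kg) is the appropriate comminution law at
submicron product sizes, where energy scales with new surface.  C_R is
tied to the Bond coefficient by C_R = 0.5 C_B d_BL with C_B = 10 BWI and
d_BL the Bond/Rittinger crossover size (default 70 µm, configurable).
Because the five BWI correction factors behind the published operating
energy are not recoverable, design-space sweeps instead calibrate C_R
once to the validated operating point (2600 kJ/kg taking a 100 µm feed to
the centre of the 300–500 nm product band) and vary energy/diameter from
there.  The published energy is printed in two unit systems that disagree
(2600 kJ/kg vs 702 kWh/ton; 2600 kJ/kg = 722.2 kWh/ton); kJ/kg is primary
and both are stored.

The RRSB distribution uses the steepness convention x = d25/d75 ∈ (0, 1),
so n = ln(ln 0.75/ln 0.25)/ln x > 0; d₆₃ = d₅₀/(ln 2)^(1/n) pins the
median exactly.  Quantiles are closed-form and are checked against
numerical CDF inversion.

Planetary kinematics: the critical angular speed zeroes the net force on
material at the top of the jar under the machine's centripetal field
(95 g for the reference device) plus gravity against the centrifugal
term: ω_c = √((G+1)g/r); operation at ω = 0.65 ω_c; jar revolution
counter-rotates (Ω = −ω).  With the jar radius read as half the 15 cm
mill diameter this gives 695.4 rpm against the published 691 rpm (0.6 %;
the exact radius convention of the published figure is not stated).  The
charge model m_B = 1500 m_i per hour of residence is retained verbatim as
an empirical loading rule; power uses the specific-power reading
P = E m_B/t_B (the literal product E·m_B is dimensionally inconsistent
when E is a specific energy), with t_B = 1 h, the batch cycle time.

## Spray dryer

Steady-state, dry-basis balances with one shared outlet temperature:
moisture Y F_g + X F_s conserved; enthalpies with constant heat
capacities (air 1006, water vapor 1860, liquid water 4186, solids
1200 J/(kg·K)) referenced to 0 °C, latent heat 2501 kJ/kg carried by
gas-phase moisture; Q_loss defaults to 0 — no property values are
published for this system, so all are configurable defaults.  The outlet
solver first assumes complete drying (X_out = 0, Y_out from the mass
balance, T_out from a bracketed root of the energy residual); if the
outlet gas would be oversaturated — or no full-drying root exists — the
outlet is pinned at saturation (RH = 1) and the residual particle
moisture follows from the mass balance.  This reproduces the
flow-dependent critical inlet temperature above which residual moisture
vanishes, and the monotone trends in inlet temperature, gas flow and
pressure.

Psychrometrics use the two-range Antoine correlation for water
(log₁₀ P/mmHg = 8.07131 − 1730.63/(233.426 + T) below 100 °C, second
range above), which recovers 1 atm at 100 °C within 0.1 %.  RH = y_m
P/P⁰(T).

The falling-rate curve v = 2F u − (2F − 1)u², u = X_w/X_w,crit, is
bounded on [0, 1] with v(1) = 1 for any shape factor F ∈ [0, 1]; above
the critical moisture the droplet is in the constant-rate period (v = 1).
The dried-particle diameter d_p = (m_s(1/ρ_s + X_d/ρ_l)·6/π)^(1/3)
freezes at the critical moisture; the solid mass per droplet comes from
an initial droplet diameter proportional to the nozzle orifice
(proportionality constant a calibration input — no atomization
correlation is published).  The critical wet-basis moisture defaults to
0.10.

## PC-SAFT

Full perturbed-chain SAFT: hard-chain (BMCSL hard-sphere mixture plus the
chain connectivity term), dispersion with the original universal
integral constants, and Wertheim first-order association with a 2-site
donor/acceptor ("2B") topology per associating component.  Temperature
dependent diameters d_i = σ_i(1 − 0.12 exp(−3ε_i/kT)); Berthelot–Lorentz
combining rules with binary k_ij; Wolbach–Sandler rules for cross
association (switchable per pair; the shipped topology enables
water–water only, since the stabilizer's mole fraction is below 0.01 and
the API does not self-associate).

The unbonded site fractions satisfy X_i = 1/(1 + Σ_j ρ_j X_j Δ_ij) with
Δ from the hard-sphere contact value; the solver is damped successive
substitution (damping 0.5, tolerance 1e-12, 500 iterations max) with the
closed form X = (−1 + √(1 + 4ρΔ))/(2ρΔ) used directly whenever a single
component associates.

**Derivatives.**  Pressure and chemical potentials come from complex-step
differentiation of a_res (step 1e-200), which is exact to machine
precision and avoids hand-coding the long analytic derivatives; central
finite differences serve as the independent consistency check in the
tests (agreement ≤ 1e-6 relative), and a separately hand-transcribed
scalar implementation of the same equations acts as a term-by-term
oracle.  ln φ_i = ∂(n a_res)/∂n_i|_(T,V) − ln Z; activity coefficients
γ_i = φ_i/φ_i⁰ against the pure-liquid reference at the same T, P.

**Density.**  P(ρ) = P is solved by scanning packing fraction over
(1e-12, 0.70), bracketing sign changes and polishing with Brent; the
liquid branch is the densest root, vapor the least dense.  Packing
fractions ≥ 0.74 are rejected.  With the shipped water parameters the
ambient liquid density is 986 kg/m³, 1.1 % from the experimental
997 kg/m³ — typical of 2B water parameterizations rounded to the printed
precision.

**Parameter defects.**  The published fenofibrate row carries ε/k = 0
(and κ^AB = 0.02 with ε^AB = 0), which would null its dispersion term;
the data file preserves the row verbatim and applies an override
(default ε/k = 250 K, a literature-typical magnitude for a drug-like
molecule, provenance-tagged as an estimate).  HPMC's m = 595.4 is
treated as segments per chain.  Because ε/k for the API is an estimate,
absolute solubilities are not quantitative — see Limitations.

## SLE and nanoparticle solubility enhancement

Bulk solubility: x₁ = (1/γ) exp[−Δh_m/RT (1 − T/T_m) − ΔC_p/R (ln(T_m/T)
− T_m/T + 1)], solved as a damped fixed point x = f(γ(x)) (relative
tolerance 1e-8); γ from PC-SAFT at the saturated composition.  At the
hydrophobic-API dilutions involved the fixed point converges in a few
iterations.

Surface tension of the API/water interface from the empirical solubility
rule γ [mN/m] = −0.33 (k_B T/v_m^(2/3)) ln(S₀/55.6) + 5, with v_m = V_m/N_A
the molecular volume, the kinetic factor expressed in mN/m, and 55.6
mol/L the molarity of pure water (S₀/55.6 a mole-fraction proxy).  For
fenofibrate-like inputs this gives ≈ 41 mN/m.

Gibbs energy enhancement of a stabilizer-coated nanoparticle of radius r
(radius, not diameter — the convention is flagged in config):

* curvature term G_ms = 2γV_m/r (1 − C/r), C = 1.5 (V_m/N_A)^(1/3)
  ≈ 1.2 nm, valid for r > C;
* interface term G_mi = 1.7 (ε_API/ε_sA)(σ_API σ_sA ρ_stab Δ/m_stab)
  γV_m/r, the only grouping of the published factor string whose
  prefactor is dimensionless (lengths σσρΔ ~ m·m·m⁻³·m, energies
  cancel); the grouping is config-switchable for sensitivity studies.

K₂/K₁ = exp(GEE/RT) exactly, and the enhanced solubility
x₂ = K a x₁/(a − x₁ + K x₁) is the stationary point of first-order
dissolution kinetics with the scaled equilibrium constant (ν = 1), which
the tests verify by brute force.

## Shipped defaults and what the tests do and do not show

Every constant not printed in the source tables lives in
`data/defaults.yaml` with a provenance note: fenofibrate melting data
(T_m = 353.15 K printed; Δh_m = 33.1 kJ/mol and ΔC_p = 110 J/(mol·K)
estimates), S₀ = 2.2·10⁻⁶ mol/L, V_m = 306 cm³/mol, HPMC bulk density
1300 kg/m³ and M_w = 13 kg/mol, inter-layer distance Δ = 5 Å, dryer heat
capacities and feed (5 kg/h dry solids at 10 wt%), X_w,crit = 0.10,
d_BL = 70 µm, the 1500× loading rule.  The synthetic stiffness generator
(isotropic/cubic/orthorhombic/random-SPD with eigenvalues clipped to
[0.5, 50] GPa) emulates stable crystalline tensors across symmetry
classes; it does not emulate the correlations of real organic crystals,
so property tests certify the tensor algebra, not any material.

Test problem sizes are chosen for thorough yet quick runs: 1000-tensor
bound sweeps, 100-draw quantile and kinetic-equilibrium oracles, 4×3
solubility grids, ~minute-scale overall.

## Known limitations

* Absolute solubilities (and hence the absolute solubility-enhancement
  surface) inherit the uncertainty of the estimated API dispersion
  energy, melting enthalpy and S₀; only the monotone shapes in r and T
  and the mild-above-150 nm / steep-below-50 nm contrast are asserted.
* The dryer model is a single equilibrium stage with constant
  properties; no droplet-population or CFD resolution, no
  crystallization during drying.
* Comminution uses a single Rittinger coefficient; no breakage
  population balance, media-motion or slurry-rheology effects.
* The PC-SAFT implementation covers liquid-phase fugacities for SLE; no
  flash algorithms, polar/ionic extensions or parameter regression.
* Published directional linear-compressibility extrema for the worked
  API are mutually inconsistent as averages (one is negative while the
  accompanying text asserts non-negative compressibility); LC output is
  therefore reported as directional extrema and not reconciled.
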