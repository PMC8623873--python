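"""Nanoparticle solubility: solid-liquid equilibria plus interfacial
Gibbs-energy enhancement.

Bulk solubility of the crystalline API comes from the classical SLE
relation

    x1 = (1/gamma) exp[-dHm/(RT) (1 - T/Tm) - dCp/R (ln(Tm/T) - Tm/T + 1)],

with the activity coefficient gamma from PC-SAFT.  A stabilizer-coated
nanoparticle dissolves more readily than the bulk crystal; the extra
driving force is modelled as a Gibbs energy enhancement

    GEE = G_ms + G_mi,          K2/K1 = exp(GEE / RT),

where G_ms = 2 gamma_s Vm/r (1 - C/r) is the curvature (surface) term of an
Ostwald-Freundlich type and G_mi is the stabilizer-interface term.  The
enhanced solubility follows from the first-order dissolution equilibrium:

    x2 = (K2/K1) a x1 / (a - x1 + (K2/K1) x1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import K_BOLTZMANN, N_AVOGADRO, R_GAS
from .pcsaft import Mixture, PureComponentParams, combining_rules

__all__ = [
    "SolidProperties",
    "NanoparticleSpec",
    "StabilizerSpec",
    "GEEResult",
    "sle_solubility",
    "surface_tension",
    "gee",
    "enhanced_solubility",
    "solubility_surface",
]

_WATER_MOLARITY = 55.6  # mol/L, pure water reference for the mole-fraction proxy


@dataclass(frozen=True)
class SolidProperties:
    """Melting data of the pure API: T_m (K), dH_m (J/mol), dCp (J/mol/K)."""

    T_m: float
    dH_m: float
    dCp: float = 0.0

    def __post_init__(self):
        if self.T_m <= 0 or self.dH_m <= 0:
            raise ValueError("T_m and dH_m must be positive")


@dataclass(frozen=True)
class StabilizerSpec:
    """Stabilizer (polymer) interface data.

    rho_bulk: kg/m^3; Mw: kg/mol; m_stab: PC-SAFT segments per chain;
    Delta_layer: inter-layer molecular distance, m.  The number density
    rho_number = rho_bulk N_A / Mw (1/m^3) is derived.
    """

    rho_bulk: float
    Mw: float
    m_stab: float
    Delta_layer: float

    @property
    def rho_number(self) -> float:
        return self.rho_bulk * N_AVOGADRO / self.Mw


def surface_tension(T: float, Vm: float, S0: float,
                    prefactor: float = 0.33, offset_mN_m: float = 5.0) -> float:
    """API/water interfacial tension (N/m) from an empirical solubility rule.

    gamma [mN/m] = -prefactor * (k_B T / v_m^(2/3)) * ln(S0 / 55.6) + offset,
    where v_m = Vm/N_A is the molecular volume (m^3), S0 the aqueous
    solubility in mol/L and 55.6 mol/L the molarity of pure water (so
    S0/55.6 is a mole-fraction proxy).  The kinetic factor k_B T / v_m^(2/3)
    is itself expressed in mN/m.
    """
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    vm = Vm / N_AVOGADRO
    kt_term = K_BOLTZMANN * T / vm ** (2.0 / 3.0) * 1e3  # J/m^2 -> mN/m
    gamma_mN = -prefactor * kt_term * np.log(S0 / _WATER_MOLARITY) + offset_mN_m
    return gamma_mN * 1e-3


@dataclass(frozen=True)
class NanoparticleSpec:
    """API nanoparticle data: radius r (m), molar volume Vm (m^3/mol),
    aqueous solubility S0 (mol/L); gamma and the curvature cut-off C are
    derived at a given temperature."""

    r: float
    Vm: float
    S0: float

    def C_param(self) -> float:
        """Curvature cut-off C = 1.5 (Vm/N_A)^(1/3), m."""
        return 1.5 * (self.Vm / N_AVOGADRO) ** (1.0 / 3.0)

    def gamma(self, T: float) -> float:
        return surface_tension(T, self.Vm, self.S0)


@dataclass(frozen=True)
class GEEResult:
    G_ms: float
    G_mi: float
    K_ratio: float
    T: float

    @property
    def GEE(self) -> float:
        return self.G_ms + self.G_mi


def gee(r: float, T: float, nano: NanoparticleSpec, stab: StabilizerSpec,
        api: PureComponentParams, stab_params: PureComponentParams,
        kij: float = 0.0) -> GEEResult:
    """Gibbs energy enhancement of a stabilizer-coated nanoparticle (J/mol).

    G_ms = 2 gamma Vm / r (1 - C/r) is the nanoparticle surface term;
    G_mi = 1.7 (eps_API/eps_sA) (sigma_API sigma_sA rho_stab Delta / m_stab)
           * gamma Vm / r
    is the stabilizer-interface term, with the cross parameters eps_sA,
    sigma_sA from the Berthelot-Lorentz rules (the bracketed groups are
    dimensionless).  K2/K1 = exp(GEE/RT).
    """
    if r <= 0:
        raise ValueError("r must be positive")
    C = nano.C_param()
    if r <= C:
        raise ValueError(f"particle radius {r} m must exceed C = {C:.3e} m")
    cross = combining_rules(api, stab_params, kij)
    if cross["eps_ij_k"] <= 0:
        raise ValueError(
            "cross dispersion energy eps_stab-API is zero; supply a non-zero "
            "API dispersion energy (see the parameter override in the data files)")
    gam = nano.gamma(T)
    g_vm_r = gam * nano.Vm / r
    G_ms = 2.0 * g_vm_r * (1.0 - C / r)
    dimless = (api.eps_k / cross["eps_ij_k"]) * (
        (api.sigma * 1e-10) * (cross["sigma_ij"] * 1e-10)
        * stab.rho_number * stab.Delta_layer / stab.m_stab)
    G_mi = 1.7 * dimless * g_vm_r
    GEE_val = G_ms + G_mi
    return GEEResult(G_ms=G_ms, G_mi=G_mi,
                     K_ratio=float(np.exp(GEE_val / (R_GAS * T))), T=T)


def enhanced_solubility(x1: float, a: float, K_ratio: float) -> float:
    """Enhanced mole-fraction solubility of the nanoparticulate API.

    x2 = K a x1 / (a - x1 + K x1) with K = K2/K1; ``a`` is the initial solid
    loading (mole fraction) before equilibrium.
    """
    if not (a > x1 > 0):
        raise ValueError("require a > x1 > 0")
    if K_ratio < 1.0:
        raise ValueError("K_ratio must be >= 1")
    den = a - x1 + K_ratio * x1
    if den <= 0:
        raise ValueError("non-physical denominator in solubility enhancement")
    return K_ratio * a * x1 / den


def ideal_sle_solubility(T: float, solid: SolidProperties) -> float:
    """SLE solubility with gamma = 1 (ideal-solution reference)."""
    if T > solid.T_m:
        raise ValueError("T must not exceed the melting temperature")
    arg = (-solid.dH_m / (R_GAS * T) * (1.0 - T / solid.T_m)
           - solid.dCp / R_GAS
           * (np.log(solid.T_m / T) - solid.T_m / T + 1.0))
    return float(np.exp(arg))


def sle_solubility(T: float, solid: SolidProperties, mixture: Mixture,
                   solute: str, solvent_x: dict,
                   P: float = 101325.0, tol: float = 1e-8,
                   damping: float = 0.5, maxiter: int = 200) -> float:
    """Mole-fraction solubility of the API from SLE with PC-SAFT activity.

    Solves the fixed point x = f(gamma(x)): starting from the ideal
    solution, the activity coefficient of ``solute`` is evaluated in the
    saturated liquid (solvent composition ``solvent_x`` rescaled around the
    solute) and damped until |dx|/x < tol.
    """
    x_ideal = ideal_sle_solubility(T, solid)
    names = mixture.names
    i_solute = names.index(solute)
    base = np.array([solvent_x.get(nm, 0.0) for nm in names], dtype=float)
    base[i_solute] = 0.0
    base = base / base.sum()

    x_sol = x_ideal  # gamma = 1 start
    for _ in range(maxiter):
        comp = base * (1.0 - x_sol)
        comp[i_solute] = x_sol
        gam = mixture.fugacity_activity(T, P, comp)["gamma"][solute]
        x_new = x_ideal / gam
        if abs(x_new - x_sol) / max(x_new, 1e-300) < tol:
            return x_new
        x_sol = damping * x_new + (1.0 - damping) * x_sol
    raise RuntimeError(f"SLE fixed point did not converge within {maxiter} iterations")


def solubility_surface(r_grid, T_grid, solid: SolidProperties,
                       nano: NanoparticleSpec, stab: StabilizerSpec,
                       api: PureComponentParams, stab_params: PureComponentParams,
                       mixture: Mixture, solute: str, solvent_x: dict,
                       a_loading: float, kij: float = 0.0) -> pd.DataFrame:
    """x2(r, T) over a grid; returns columns r, T, x1, K_ratio, x2.

    The nanoparticle spec's radius field is overridden by each grid value.
    """
    rows = []
    for T in np.atleast_1d(T_grid):
        x1 = sle_solubility(T, solid, mixture, solute, solvent_x)
        for r in np.atleast_1d(r_grid):
            res = gee(float(r), float(T), nano, stab, api, stab_params, kij)
            x2 = enhanced_solubility(x1, a_loading, res.K_ratio)
            rows.append({"r": float(r), "T": float(T), "x1": x1,
                         "K_ratio": res.K_ratio, "x2": x2})
    return pd.DataFrame(rows)
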