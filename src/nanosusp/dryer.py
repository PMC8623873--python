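"""Steady-state spray-dryer balances, outlet equilibrium and psychrometrics.

Streams are described on a dry basis: a gas stream carries Y kg of moisture
per kg of dry gas, a suspension stream X kg of moisture per kg of dry
solids.  Enthalpies use constant heat capacities with a 0 degC reference and
the latent heat of vaporization dHv0 assigned to the gas-phase moisture:

    H_gas = F_gas,dry ((Cp_gas,dry + Y Cp_w) T + Y dHv0)
    H_s   = F_s,dry  (Cp_s,dry + X Cp_w,liq) T

The outlet equilibrium couples the mass and energy balances under a single
outlet temperature shared by gas and solids; residual particle moisture
appears only when the outlet gas saturates before the feed water is
exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GasStream",
    "SuspensionStream",
    "DryerSpec",
    "mass_balance",
    "energy_balance",
    "solve_outlet_equilibrium",
    "evaporation_rate",
    "particle_diameter",
    "relative_humidity",
    "water_vapor_pressure",
    "saturation_humidity",
]

MW_WATER = 18.01528   # g/mol
MW_AIR = 28.9647      # g/mol

# Antoine constants for water, log10(P/mmHg) = A - B/(C + T[degC])
_ANTOINE_LOW = (8.07131, 1730.63, 233.426)   # 1..100 degC
_ANTOINE_HIGH = (8.14019, 1810.94, 244.485)  # 100..374 degC
_MMHG_TO_PA = 101325.0 / 760.0


@dataclass(frozen=True)
class GasStream:
    """Drying-gas stream: dry-basis flow (kg/h), moisture Y (kg/kg dry),
    temperature (degC), pressure (Pa) and heat capacities (J/kg/K)."""

    F_dry: float
    Y: float
    T: float
    P: float = 101325.0
    Cp_dry: float = 1006.0
    Cp_w: float = 1860.0   # water vapor

    def __post_init__(self):
        if self.Y < 0:
            raise ValueError("gas moisture Y must be non-negative")

    @property
    def y_m(self) -> float:
        """Moisture mole fraction in the gas."""
        nw = self.Y / MW_WATER
        return nw / (nw + 1.0 / MW_AIR)

    def enthalpy(self, dHv0: float) -> float:
        """Stream enthalpy, W (0 degC reference)."""
        return self.F_dry / 3600.0 * (
            (self.Cp_dry + self.Y * self.Cp_w) * self.T + self.Y * dHv0)


@dataclass(frozen=True)
class SuspensionStream:
    """Solids/suspension stream: dry-solids flow (kg/h), dry-basis moisture X,
    temperature (degC)."""

    F_dry: float
    X: float
    T: float
    Cp_s_dry: float = 1200.0
    Cp_w_liq: float = 4186.0

    def __post_init__(self):
        if self.X < 0:
            raise ValueError("solids moisture X must be non-negative")

    @property
    def Xw(self) -> float:
        """Wet-basis moisture, X/(1+X)."""
        return self.X / (1.0 + self.X)

    def enthalpy(self, dHv0: float = 0.0) -> float:
        """Stream enthalpy, W (liquid moisture carries no latent term)."""
        return self.F_dry / 3600.0 * (self.Cp_s_dry + self.X * self.Cp_w_liq) * self.T


@dataclass(frozen=True)
class DryerSpec:
    """Dryer hardware/energy data: nozzle orifice D_n (m), heater duty and
    losses (W), reference latent heat (J/kg), evaporation shape factor."""

    D_n: float
    Q_in: float = 0.0
    Q_loss: float = 0.0
    dHv0: float = 2.501e6
    F_shape: float = 0.5

    def __post_init__(self):
        if self.D_n <= 0:
            raise ValueError("nozzle diameter must be positive")
        if not (0.0 <= self.F_shape <= 1.0):
            raise ValueError("shape factor must lie in [0, 1]")


def mass_balance(gas_in: GasStream, susp_in: SuspensionStream,
                 Y_out: float | None = None, X_out: float | None = None) -> dict:
    """Close the dry-basis moisture balance for the single unknown.

    Y_in F_gas + X_in F_s = Y_out F_gas + X_out F_s.  Exactly one of
    ``Y_out``/``X_out`` must be None (the unknown).
    """
    if (Y_out is None) == (X_out is None):
        raise ValueError("exactly one of Y_out, X_out must be unknown")
    Fg, Fs = gas_in.F_dry, susp_in.F_dry
    total = gas_in.Y * Fg + susp_in.X * Fs
    if Y_out is None:
        Y_out = (total - X_out * Fs) / Fg
    else:
        X_out = (total - Y_out * Fg) / Fs
    return {"Y_out": Y_out, "X_out": X_out,
            "residual": gas_in.Y * Fg + susp_in.X * Fs - Y_out * Fg - X_out * Fs}


def energy_balance(gas_in: GasStream, susp_in: SuspensionStream,
                   gas_out: GasStream, susp_out: SuspensionStream,
                   spec: DryerSpec, unknown: str = "T_out") -> float:
    """Solve the overall enthalpy balance for one unknown.

    0 = H_gas,in + H_s,in + Q_in - H_gas,out - H_s,out - Q_loss.
    ``unknown`` is ``"T_out"`` (shared outlet temperature, solved by
    bracketed root finding; the outlet stream temperatures are ignored) or
    ``"Q_in"`` (returned directly from the residual).
    """
    H_in = gas_in.enthalpy(spec.dHv0) + susp_in.enthalpy() + spec.Q_in - spec.Q_loss

    def residual(T):
        return (H_in
                - replace(gas_out, T=T).enthalpy(spec.dHv0)
                - replace(susp_out, T=T).enthalpy())

    if unknown == "Q_in":
        return (gas_out.enthalpy(spec.dHv0) + susp_out.enthalpy() + spec.Q_loss
                - gas_in.enthalpy(spec.dHv0) - susp_in.enthalpy())
    if unknown != "T_out":
        raise ValueError(f"unsupported unknown {unknown!r}")
    lo, hi = -50.0, max(gas_in.T, susp_in.T, 50.0) + 300.0
    if residual(lo) * residual(hi) > 0:
        raise RuntimeError("infeasible operating point: no outlet-temperature bracket")
    return brentq(residual, lo, hi, xtol=1e-10, rtol=1e-14)


def water_vapor_pressure(T: float) -> float:
    """Saturation vapor pressure of water, Pa, from Antoine correlations
    (two ranges joined at 100 degC; valid 1..374 degC)."""
    if not (1.0 <= T <= 374.0):
        raise ValueError(f"temperature {T} degC outside Antoine range 1..374")
    A, B, C = _ANTOINE_LOW if T <= 100.0 else _ANTOINE_HIGH
    return 10.0 ** (A - B / (C + T)) * _MMHG_TO_PA


def relative_humidity(y_m: float, P: float, T: float) -> float:
    """RH = y_m P / P0(T): moisture partial pressure over saturation pressure."""
    if P <= 0:
        raise ValueError("P must be positive")
    return y_m * P / water_vapor_pressure(T)


def saturation_humidity(T: float, P: float) -> float:
    """Dry-basis moisture of saturated air, kg water / kg dry air."""
    p0 = water_vapor_pressure(T)
    if p0 >= P:
        return np.inf
    return (MW_WATER / MW_AIR) * p0 / (P - p0)


def solve_outlet_equilibrium(gas_in: GasStream, susp_in: SuspensionStream,
                             spec: DryerSpec) -> dict:
    """Simultaneous mass/energy closure with one shared outlet temperature.

    First tries complete drying (X_out = 0, Y_out from the mass balance); if
    the resulting outlet gas would be oversaturated, the outlet is pinned at
    saturation instead (Y_out = Y_sat(T_out)) and the residual moisture
    follows from the mass balance.
    """
    Fg, Fs = gas_in.F_dry, susp_in.F_dry

    # regime 1: full evaporation (may be infeasible when the gas is starved)
    mb = mass_balance(gas_in, susp_in, X_out=0.0)
    gas_out = replace(gas_in, Y=mb["Y_out"], T=25.0)
    susp_out = replace(susp_in, X=0.0, T=25.0)
    try:
        T_out = energy_balance(gas_in, susp_in, gas_out, susp_out, spec)
        rh = relative_humidity(replace(gas_out, T=T_out).y_m, gas_in.P,
                               float(np.clip(T_out, 1.0, 374.0)))
        if rh <= 1.0 and 1.0 <= T_out <= 374.0:
            return {"T_out": T_out, "X_out": 0.0, "Y_out": mb["Y_out"],
                    "RH_out": rh, "regime": "dry"}
    except RuntimeError:
        pass  # no full-drying root: resolve against the saturated outlet

    # regime 2: saturated outlet, residual moisture remains
    H_in = gas_in.enthalpy(spec.dHv0) + susp_in.enthalpy() + spec.Q_in - spec.Q_loss

    def residual(T):
        Y = saturation_humidity(T, gas_in.P)
        X = max((gas_in.Y - Y) * Fg / Fs + susp_in.X, 0.0)
        return (H_in - replace(gas_in, Y=Y, T=T).enthalpy(spec.dHv0)
                - replace(susp_in, X=X, T=T).enthalpy())

    T_out = brentq(residual, 1.0, float(np.clip(max(gas_in.T, 50.0) + 200.0, 2.0, 373.9)),
                   xtol=1e-10, rtol=1e-14)
    Y_out = saturation_humidity(T_out, gas_in.P)
    X_out = max((gas_in.Y - Y_out) * Fg / Fs + susp_in.X, 0.0)
    return {"T_out": T_out, "X_out": X_out, "Y_out": Y_out, "RH_out": 1.0,
            "regime": "saturated"}


def evaporation_rate(Xw: float, Xw_crit: float, F: float) -> float:
    """Normalized falling-rate evaporation curve.

    v = 2F u - (2F - 1) u^2 with u = Xw/Xw_crit.  Above the critical
    moisture (u > 1) the droplet is in the constant-rate period and v = 1.
    """
    if not (0.0 <= F <= 1.0):
        raise ValueError("shape factor must lie in [0, 1]")
    if Xw < 0 or Xw_crit <= 0:
        raise ValueError("moisture contents must be non-negative (Xw_crit > 0)")
    u = Xw / Xw_crit
    if u > 1.0:
        return 1.0
    return 2.0 * F * u - (2.0 * F - 1.0) * u * u


def particle_diameter(m_s: float, X_d: float, rho_s: float, rho_l: float) -> float:
    """Dried-particle diameter, m: d_p = (m_s (1/rho_s + X_d/rho_l) 6/pi)^(1/3).

    ``X_d`` is the dry-basis moisture at which the diameter freezes (the
    critical moisture content); m_s is the solid mass per droplet (kg).
    """
    if min(m_s, rho_s, rho_l) <= 0 or X_d < 0:
        raise ValueError("inputs must be positive (X_d >= 0)")
    return (m_s * (1.0 / rho_s + X_d / rho_l) * 6.0 / np.pi) ** (1.0 / 3.0)


def droplet_solid_mass(D_n: float, k_droplet: float, rho_slurry: float,
                       w_solids: float) -> float:
    """Solid mass per atomized droplet, kg.

    The initial droplet diameter is taken proportional to the nozzle
    orifice, d_d = k_droplet D_n (the proportionality constant is a
    calibration input); m_s = (pi/6) d_d^3 rho_slurry w_solids.
    """
    d_d = k_droplet * D_n
    return np.pi / 6.0 * d_d ** 3 * rho_slurry * w_solids
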