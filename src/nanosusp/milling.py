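"""Wet-media milling design space.

Comminution energy follows Rittinger's law (energy proportional to new
surface, appropriate at the nanoscale),

    E = C_R (1/d_p - 1/d_f),   d in um, E in kWh/ton,

with the Rittinger coefficient tied to the Bond Work Index through the Bond
coefficient C_B = 10 BWI and the Bond-range limit size d_BL.  The product
size distribution is the RRSB (Rosin-Rammler-Sperling-Bennet, i.e. Weibull)
cumulative form Q(d) = 1 - exp(-(d/d63)^n).  Planetary ball-mill kinematics
set the operating speed at 65% of the critical speed at which the net force
on material at the top of the jar vanishes under the machine's centripetal
field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import G_STANDARD, KWH_PER_TON_TO_KJ_PER_KG

__all__ = [
    "ComminutionParams",
    "MillDesign",
    "PSD",
    "rittinger_energy",
    "invert_rittinger",
    "calibrate_cr",
    "rrsb_from_median",
    "planetary_kinematics",
    "design_space_sweep",
]


@dataclass(frozen=True)
class ComminutionParams:
    """Comminution coefficients: BWI (kWh/ton), C_B = 10 BWI, d_BL (um),
    C_R = 0.5 C_B d_BL (kWh um / ton)."""

    BWI: float
    d_BL: float = 70.0

    def __post_init__(self):
        if self.BWI <= 0 or self.d_BL <= 0:
            raise ValueError("BWI and d_BL must be positive")

    @property
    def C_B(self) -> float:
        return 10.0 * self.BWI

    @property
    def C_R(self) -> float:
        return 0.5 * self.C_B * self.d_BL


def rittinger_energy(d80_in: float, d80_out: float, C_R: float) -> dict:
    """Specific comminution energy for d80_in -> d80_out (sizes in um).

    Returns the energy in both kWh/ton and kJ/kg (1 kWh/ton = 3.6 kJ/kg).
    """
    if d80_out <= 0 or d80_in <= 0:
        raise ValueError("sizes must be positive")
    if d80_out >= d80_in:
        raise ValueError("no comminution: product size must be below feed size")
    E = C_R * (1.0 / d80_out - 1.0 / d80_in)
    return {"E_kWh_ton": E, "E_kJ_kg": E * KWH_PER_TON_TO_KJ_PER_KG}


def invert_rittinger(E_kWh_ton: float, d80_in: float, C_R: float) -> float:
    """Product size d80_out (um) for a given specific energy (kWh/ton)."""
    if E_kWh_ton < 0:
        raise ValueError("energy must be non-negative")
    return 1.0 / (E_kWh_ton / C_R + 1.0 / d80_in)


def calibrate_cr(E_kWh_ton: float, d80_in: float, d80_out: float) -> float:
    """Rittinger coefficient reproducing a known operating point."""
    return E_kWh_ton / (1.0 / d80_out - 1.0 / d80_in)


@dataclass(frozen=True)
class PSD:
    """RRSB (Weibull) particle size distribution: scale d63, shape n.

    Q(d63) = 1 - 1/e by construction; quantiles invert the closed form.
    Sizes carry whatever unit d63 carries.
    """

    d63: float
    n: float

    def __post_init__(self):
        if self.d63 <= 0 or self.n <= 0:
            raise ValueError("d63 and n must be positive")

    def cdf(self, d):
        d = np.asarray(d, dtype=float)
        return np.where(d <= 0, 0.0, 1.0 - np.exp(-((d / self.d63) ** self.n)))

    def quantile(self, q):
        q = np.asarray(q, dtype=float)
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("quantile levels must lie in (0, 1)")
        return self.d63 * (-np.log(1.0 - q)) ** (1.0 / self.n)

    @property
    def d50(self) -> float:
        return float(self.quantile(0.5))

    @property
    def d80(self) -> float:
        return float(self.quantile(0.8))


def rrsb_from_median(d50: float, x_steepness: float) -> PSD:
    """Construct an RRSB distribution from the median and steepness x = d25/d75.

    n = ln(ln 0.75 / ln 0.25) / ln(x) (positive for x < 1);
    d63 = d50 / (ln 2)^(1/n), which pins Q(d50) = 0.5 exactly.
    """
    if not (0.0 < x_steepness < 1.0):
        raise ValueError("steepness x = d25/d75 must lie in (0, 1)")
    n = np.log(np.log(0.75) / np.log(0.25)) / np.log(x_steepness)
    d63 = d50 / np.log(2.0) ** (1.0 / n)
    return PSD(d63=d63, n=float(n))


@dataclass(frozen=True)
class MillDesign:
    """Planetary ball-mill geometry and loading.

    D_m: jar diameter, m; g_factor: centripetal field in multiples of g
    (95 for the reference device); t_B: residence time, s; m_i: mass of the
    material element at the top ("red spot") of the jar, kg; load_factor:
    empirical ratio of total charge to red-spot mass per hour of residence.
    """

    D_m: float
    g_factor: float = 95.0
    t_B: float = 3600.0
    m_i: float = 45.3e-6
    load_factor: float = 1500.0

    @property
    def r(self) -> float:
        return 0.5 * self.D_m


def planetary_kinematics(design: MillDesign, E_kJ_kg: float | None = None) -> dict:
    """Critical and operating speeds, charge mass, power and torque.

    At the top of the jar the net force vanishes at the critical speed:
    m_i omega_c^2 r = (g_factor + 1) m_i g, so omega_c = sqrt((g_factor+1) g / r).
    Operating speed omega = 0.65 omega_c; the jar revolution counter-rotates,
    Omega = -omega.  Charge mass m_B = load_factor * m_i * (t_B / 1 h); if a
    specific energy E (kJ/kg) is given, power P = E m_B / t_B and torque
    tau = P / omega.
    """
    if design.r <= 0 or design.g_factor <= 0:
        raise ValueError("jar radius and g-factor must be positive")
    omega_c = np.sqrt((design.g_factor + 1.0) * G_STANDARD / design.r)
    omega = 0.65 * omega_c
    m_B = design.load_factor * design.m_i * (design.t_B / 3600.0)
    out = {
        "omega_c_rad_s": float(omega_c),
        "omega_rad_s": float(omega),
        "omega_rpm": float(omega * 60.0 / (2.0 * np.pi)),
        "Omega_rad_s": float(-omega),
        "m_B_kg": float(m_B),
    }
    if E_kJ_kg is not None:
        P = E_kJ_kg * 1e3 * m_B / design.t_B
        out["power_W"] = float(P)
        out["torque_N_m"] = float(P / omega)
    return out


def red_spot_residual(design: MillDesign, omega: float) -> float:
    """Net force (N) on the red-spot element at angular speed omega (rad/s):
    centripetal field + weight - centrifugal term.  Zero at omega_c."""
    return design.m_i * (design.g_factor * G_STANDARD + G_STANDARD
                         - omega ** 2 * design.r)


def design_space_sweep(E_grid_kJ_kg, d80_in_um: float, C_R: float) -> pd.DataFrame:
    """Product d80 (nm) over a specific-energy grid (kJ/kg)."""
    rows = []
    for E in np.atleast_1d(E_grid_kJ_kg):
        E_kwh = float(E) / KWH_PER_TON_TO_KJ_PER_KG
        d80_out = invert_rittinger(E_kwh, d80_in_um, C_R)
        rows.append({"E_kJ_kg": float(E), "E_kWh_ton": E_kwh,
                     "d80_out_um": d80_out, "d80_out_nm": d80_out * 1e3})
    return pd.DataFrame(rows)
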