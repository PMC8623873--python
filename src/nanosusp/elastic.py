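"""Elastic-tensor analysis of a crystalline API.

Starting from a 6x6 stiffness matrix (Voigt notation, GPa) this module
computes polycrystalline Voigt/Reuss/Hill averages, directional elastic
properties, anisotropy indices, elasticity-based Vickers hardness and
fracture toughness, and finally the Bond Work Index that feeds the
comminution model.  The stiffness matrix itself is an input (from DFT or
force-field calculations); computing it is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import GPA_TO_KG_MM2, N_AVOGADRO

__all__ = [
    "StiffnessTensor",
    "PolycrystalAverages",
    "AnisotropyReport",
    "DirectionalProfile",
    "HardnessReport",
    "vrh_averages",
    "engineering_constants",
    "directional_properties",
    "anisotropy_indices",
    "vickers_hardness",
    "fracture_toughness",
    "bwi_from_hardness",
]

# Voigt index pairs: 11, 22, 33, 23, 13, 12
_VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


class StabilityError(ValueError):
    """Raised when a stiffness matrix is not mechanically stable (not SPD)."""


@dataclass(frozen=True)
class StiffnessTensor:
    """6x6 elastic stiffness matrix in GPa, Voigt notation.

    The compliance matrix ``S`` (GPa^-1) is computed on construction.
    Mechanical stability (all eigenvalues of C strictly positive) and
    symmetry are enforced.
    """

    C: np.ndarray
    S: np.ndarray = field(init=False)

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        if C.shape != (6, 6):
            raise ValueError(f"stiffness matrix must be 6x6, got {C.shape}")
        if not np.allclose(C, C.T, atol=1e-9):
            raise ValueError("stiffness matrix must be symmetric within 1e-9 GPa")
        C = 0.5 * (C + C.T)
        eig = np.linalg.eigvalsh(C)
        if eig.min() <= 0.0:
            raise StabilityError(
                f"stiffness matrix is not mechanically stable: "
                f"smallest eigenvalue {eig.min():.6g} GPa <= 0"
            )
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "S", np.linalg.inv(C))

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_text(cls, text: str) -> "StiffnessTensor":
        """Parse a whitespace-separated 6x6 matrix (ELATE-style plain text)."""
        vals = [float(tok) for tok in text.split()]
        if len(vals) != 36:
            raise ValueError(f"expected 36 numbers, got {len(vals)}")
        return cls(np.array(vals).reshape(6, 6))

    @classmethod
    def from_file(cls, path: str | Path) -> "StiffnessTensor":
        """Load from plain text (6x6 whitespace matrix) or JSON with a 'Cij' key."""
        path = Path(path)
        raw = path.read_text()
        if path.suffix.lower() == ".json" or raw.lstrip().startswith("{"):
            obj = json.loads(raw)
            return cls(np.asarray(obj["Cij"], dtype=float))
        lines = [ln for ln in raw.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
        return cls.from_text(" ".join(lines))

    # -- full 4th-rank compliance ------------------------------------------
    def compliance_tensor(self) -> np.ndarray:
        """Full S_ijkl (GPa^-1) from the Voigt compliance with 1/2 and 1/4 factors."""
        S4 = np.zeros((3, 3, 3, 3))
        for a, (i, j) in enumerate(_VOIGT_PAIRS):
            for b, (k, l) in enumerate(_VOIGT_PAIRS):
                fac = 1.0
                if a >= 3:
                    fac *= 0.5
                if b >= 3:
                    fac *= 0.5
                val = self.S[a, b] * fac
                for ii, jj in ((i, j), (j, i)):
                    for kk, ll in ((k, l), (l, k)):
                        S4[ii, jj, kk, ll] = val
        return S4


@dataclass(frozen=True)
class PolycrystalAverages:
    K_V: float
    K_R: float
    K_H: float
    G_V: float
    G_R: float
    G_H: float
    E_V: float
    E_R: float
    E_H_closed: float
    E_H_arith: float
    nu_V: float
    nu_R: float
    nu_H_closed: float
    nu_H_arith: float
    pugh_KG: float
    pugh_GK: float


@dataclass(frozen=True)
class AnisotropyReport:
    UAI: float
    A_CB: float
    A_log: float
    cauchy_pressure: float
    LC_min: float
    LC_max: float


@dataclass(frozen=True)
class DirectionalProfile:
    theta: float
    phi: float
    unit_vector: np.ndarray
    E_dir: float
    LC_dir: float
    nu_min: float
    nu_max: float
    G_min: float
    G_max: float


@dataclass(frozen=True)
class HardnessReport:
    H_mazhnik: float
    H_shear: float
    K_IC: float
    BWI0: float
    VH_kg_mm2: float


def engineering_constants(K: float, G: float) -> dict:
    """Isotropic Young's modulus, Poisson's ratio and both Pugh conventions.

    E = 9KG/(3K+G); nu = (3K-2G)/(2(3K+G)).
    """
    if K <= 0 or G <= 0:
        raise ValueError("K and G must be positive")
    E = 9.0 * K * G / (3.0 * K + G)
    nu = (3.0 * K - 2.0 * G) / (2.0 * (3.0 * K + G))
    return {"E": E, "nu": nu, "pugh_KG": K / G, "pugh_GK": G / K}


def vrh_averages(tensor: StiffnessTensor) -> PolycrystalAverages:
    """Voigt/Reuss/Hill polycrystalline moduli from stiffness/compliance contractions.

    The Voigt (uniform strain) average contracts C, the Reuss (uniform
    stress) average contracts S, and Hill is their arithmetic mean.  E and
    nu are reported in two conventions: "closed" applies the isotropic
    relations to (K_H, G_H); "arithmetic" averages the Voigt and Reuss
    E, nu directly.
    """
    C, S = tensor.C, tensor.S
    K_V = (C[0, 0] + C[1, 1] + C[2, 2] + 2.0 * (C[0, 1] + C[0, 2] + C[1, 2])) / 9.0
    G_V = (
        (C[0, 0] + C[1, 1] + C[2, 2]) - (C[0, 1] + C[0, 2] + C[1, 2])
    ) / 15.0 + (C[3, 3] + C[4, 4] + C[5, 5]) / 5.0
    K_R = 1.0 / (S[0, 0] + S[1, 1] + S[2, 2] + 2.0 * (S[0, 1] + S[0, 2] + S[1, 2]))
    G_R = 15.0 / (
        4.0 * (S[0, 0] + S[1, 1] + S[2, 2])
        - 4.0 * (S[0, 1] + S[0, 2] + S[1, 2])
        + 3.0 * (S[3, 3] + S[4, 4] + S[5, 5])
    )
    K_H = 0.5 * (K_V + K_R)
    G_H = 0.5 * (G_V + G_R)
    ev = engineering_constants(K_V, G_V)
    er = engineering_constants(K_R, G_R)
    eh = engineering_constants(K_H, G_H)
    return PolycrystalAverages(
        K_V=K_V, K_R=K_R, K_H=K_H,
        G_V=G_V, G_R=G_R, G_H=G_H,
        E_V=ev["E"], E_R=er["E"],
        E_H_closed=eh["E"], E_H_arith=0.5 * (ev["E"] + er["E"]),
        nu_V=ev["nu"], nu_R=er["nu"],
        nu_H_closed=eh["nu"], nu_H_arith=0.5 * (ev["nu"] + er["nu"]),
        pugh_KG=eh["pugh_KG"], pugh_GK=eh["pugh_GK"],
    )


def hill_from_bounds(K_V: float, K_R: float, G_V: float, G_R: float) -> dict:
    """Hill averages and both E/nu conventions from given Voigt/Reuss moduli.

    Used when the polycrystalline bounds come from an external tensor tool
    rather than from a shipped stiffness matrix.
    """
    K_H, G_H = 0.5 * (K_V + K_R), 0.5 * (G_V + G_R)
    ev, er, eh = (engineering_constants(*kg) for kg in ((K_V, G_V), (K_R, G_R), (K_H, G_H)))
    return {
        "K_H": K_H, "G_H": G_H,
        "E_H_closed": eh["E"], "nu_H_closed": eh["nu"],
        "E_H_arith": 0.5 * (ev["E"] + er["E"]),
        "nu_H_arith": 0.5 * (ev["nu"] + er["nu"]),
        "pugh_GK": eh["pugh_GK"], "pugh_KG": eh["pugh_KG"],
    }


def _unit_vector(theta: float, phi: float) -> np.ndarray:
    return np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def directional_properties(
    tensor: StiffnessTensor, theta: float, phi: float, n_chi: int = 360
) -> DirectionalProfile:
    """Directional Young's modulus, linear compressibility and transverse extrema.

    E(n) = 1/(n_i n_j n_k n_l S_ijkl); LC(n) = n_i n_j S_ijkk.  Poisson's
    ratio and shear modulus extrema are obtained by scanning the transverse
    angle chi over ``n_chi`` steps.  LC is returned in TPa^-1, moduli in GPa.
    """
    a = _unit_vector(theta, phi)
    S4 = tensor.compliance_tensor()
    E_dir = 1.0 / np.einsum("i,j,k,l,ijkl->", a, a, a, a, S4)
    LC_dir = np.einsum("i,j,ijkk->", a, a, S4) * 1e3  # GPa^-1 -> TPa^-1

    # orthonormal transverse basis
    ref = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(a, ref)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    chi = np.linspace(0.0, 2.0 * np.pi, n_chi, endpoint=False)
    m = np.outer(np.cos(chi), u) + np.outer(np.sin(chi), v)  # (n_chi, 3)

    Saamm = np.einsum("i,j,ck,cl,ijkl->c", a, a, m, m, S4)
    nus = -Saamm * E_dir
    Gamam = 4.0 * np.einsum("i,cj,k,cl,ijkl->c", a, m, a, m, S4)
    Gs = 1.0 / Gamam
    return DirectionalProfile(
        theta=theta, phi=phi, unit_vector=a,
        E_dir=E_dir, LC_dir=LC_dir,
        nu_min=float(nus.min()), nu_max=float(nus.max()),
        G_min=float(Gs.min()), G_max=float(Gs.max()),
    )


def anisotropy_indices(tensor: StiffnessTensor, n_scan: int = 60) -> AnisotropyReport:
    """Universal, Chung-Buessem and log-Euclidean anisotropy indices.

    UAI = 5 G_V/G_R + K_V/K_R - 6 (zero iff isotropic);
    A_CB = (G_V-G_R)/(G_V+G_R); A_log = sqrt(ln(K_V/K_R)^2 + 5 ln(G_V/G_R)^2).
    Cauchy pressure C12 - C44 in GPa; LC extrema from a directional scan
    (TPa^-1).
    """
    avg = vrh_averages(tensor)
    if avg.G_R <= 0:
        raise StabilityError("degenerate tensor: Reuss shear modulus <= 0")
    UAI = 5.0 * avg.G_V / avg.G_R + avg.K_V / avg.K_R - 6.0
    A_CB = (avg.G_V - avg.G_R) / (avg.G_V + avg.G_R)
    A_log = np.sqrt(
        np.log(avg.K_V / avg.K_R) ** 2 + 5.0 * np.log(avg.G_V / avg.G_R) ** 2
    )
    S4 = tensor.compliance_tensor()
    thetas = np.arccos(np.linspace(-1.0, 1.0, n_scan))
    phis = np.linspace(0.0, 2.0 * np.pi, 2 * n_scan, endpoint=False)
    tt, pp = np.meshgrid(thetas, phis, indexing="ij")
    n = np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
    ).reshape(-1, 3)
    LC = np.einsum("ci,cj,ijkk->c", n, n, S4) * 1e3
    return AnisotropyReport(
        UAI=UAI, A_CB=A_CB, A_log=float(A_log),
        cauchy_pressure=tensor.C[0, 1] - tensor.C[3, 3],
        LC_min=float(LC.min()), LC_max=float(LC.max()),
    )


def _chi_mazhnik(nu: float) -> float:
    num = 1.0 - 8.5 * nu + 19.5 * nu * nu
    den = 1.0 - 7.5 * nu + 12.2 * nu * nu + 19.6 * nu ** 3
    if den <= 0:
        raise ValueError(f"hardness correlation undefined at nu={nu}")
    return num / den


def vickers_hardness(
    E: float, nu: float, model: str = "mazhnik", G: float | None = None
) -> float:
    """Vickers hardness (GPa) from an elasticity-based model.

    ``mazhnik``: H = 0.096 chi(nu) E, the Mazhnik-Oganov correlation.
    ``shear_empirical``: H = 0.1475 G, an empirical shear-modulus
    proportionality (coefficient reverse-engineered from the ElaTools
    hardness column; see docs/methods.md).
    """
    if model == "mazhnik":
        if E <= 0 or not (0.0 <= nu < 0.5):
            raise ValueError("require E > 0 and 0 <= nu < 0.5")
        return 0.096 * _chi_mazhnik(nu) * E
    if model == "shear_empirical":
        if G is None:
            raise ValueError("shear_empirical model requires G")
        return 0.1475 * G
    raise ValueError(f"unknown hardness model {model!r}")


#: Mazhnik-Oganov fracture-toughness constants
_ALPHA0_GPA = 8840.0  # GPa


def _zeta_mazhnik(nu: float) -> float:
    num = 1.0 - 13.7 * nu + 48.6 * nu * nu
    den = 1.0 - 15.2 * nu + 70.2 * nu * nu - 81.5 * nu ** 3
    return num / den


def fracture_toughness(E: float, nu: float, V0: float) -> float:
    """Fracture toughness K_IC (MPa m^1/2) from the Mazhnik-Oganov model.

    K_IC = alpha0^(-1/2) V0^(1/6) [zeta(nu) E]^(3/2) with alpha0 = 8840 GPa
    and V0 the molecular volume in m^3.  ``V0`` has no sensible default and
    must be supplied.
    """
    if V0 is None or V0 <= 0:
        raise ValueError("molecular volume V0 (m^3) must be supplied and positive")
    if E <= 0:
        raise ValueError("E must be positive")
    alpha0 = _ALPHA0_GPA * 1e9  # Pa
    zE = _zeta_mazhnik(nu) * E * 1e9  # Pa
    k_ic = alpha0 ** -0.5 * V0 ** (1.0 / 6.0) * zE ** 1.5  # Pa m^1/2
    return k_ic / 1e6


def bwi_from_hardness(
    VH: float,
    F: tuple = (1.0, 1.0, 1.0, 1.0, 1.0),
    coeffs: tuple = (5e-6, -0.003, 9.6937),
) -> dict:
    """Bond Work Index (kWh/ton) from Vickers hardness in kg/mm^2.

    BWI0 = 5e-6 VH^2 - 0.003 VH + 9.6937 (Gent et al. quadratic), corrected
    multiplicatively: BWI = BWI0 * prod(F_i).  The five correction factors
    (open circuit, dry milling, mill diameter, inlet size, reduction ratio)
    default to unity.
    """
    if VH <= 0:
        raise ValueError("VH must be positive")
    if any(f <= 0 for f in F):
        raise ValueError("all correction factors must be positive")
    a, b, c = coeffs
    bwi0 = a * VH * VH + b * VH + c
    if bwi0 <= 0:
        raise ValueError(f"BWI0 non-positive for VH={VH} kg/mm^2")
    bwi = bwi0 * float(np.prod(F))
    return {"BWI0": bwi0, "BWI": bwi}


def hardness_report(
    E: float, nu: float, G: float, Vm_m3_mol: float,
    F: tuple = (1.0, 1.0, 1.0, 1.0, 1.0),
) -> HardnessReport:
    """Bundle hardness, toughness and BWI0 for a given elastic state.

    ``Vm_m3_mol`` is the molar volume; the molecular volume V0 = Vm/N_A
    enters the fracture-toughness model.
    """
    H = vickers_hardness(E, nu, "mazhnik")
    VH = H * GPA_TO_KG_MM2
    return HardnessReport(
        H_mazhnik=H,
        H_shear=vickers_hardness(E, nu, "shear_empirical", G=G),
        K_IC=fracture_toughness(E, nu, Vm_m3_mol / N_AVOGADRO),
        BWI0=bwi_from_hardness(VH, F)["BWI0"],
        VH_kg_mm2=VH,
    )
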