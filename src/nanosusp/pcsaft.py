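"""PC-SAFT equation of state for the API/stabilizer/water mixture.

Implements the perturbed-chain SAFT residual Helmholtz energy as the sum of
hard-chain, dispersion and association contributions,

    a_res = a_hc + a_disp + a_assoc     (all reduced by RT, per mole),

together with the density and fugacity machinery needed for solid-liquid
equilibria.  The hard-chain and dispersion terms follow the original
perturbed-chain formulation (universal dispersion-integral constants
included below); association uses the Wertheim first-order theory with a
2-site (donor/acceptor, "2B") topology per associating component.

Working units: temperatures K, segment diameters A (angstrom), molar
densities mol/m^3, pressures Pa.  Internally number densities are in A^-3.

Derivatives of a_res (for pressure and chemical potentials) are evaluated
by complex-step differentiation, which is exact to machine precision; every
routine below therefore accepts complex-valued density/composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import N_AVOGADRO, R_GAS

__all__ = [
    "PureComponentParams",
    "BinaryInteractionSet",
    "Mixture",
    "AssociationSolution",
    "ResidualEnergies",
    "combining_rules",
]

# ---------------------------------------------------------------------------
# universal dispersion-integral constants (original perturbed-chain fit)
_A0 = np.array([0.9105631445, 0.6361281449, 2.6861347891, -26.547362491,
                97.759208784, -159.59154087, 91.297774084])
_A1 = np.array([-0.3084016918, 0.1860531159, -2.5030047259, 21.419793629,
                -65.255885330, 83.318680481, -33.746922930])
_A2 = np.array([-0.0906148351, 0.4527842806, 0.5962700728, -1.7241829131,
                -4.1302112531, 13.776631870, -8.6728470368])
_B0 = np.array([0.7240946941, 2.2382791861, -4.0025849485, -21.003576815,
                26.855641363, 206.55133841, -355.60235612])
_B1 = np.array([-0.5755498075, 0.6995095521, 3.8925673390, -17.215471648,
                192.67226447, -161.82646165, -165.20769346])
_B2 = np.array([0.0976883116, -0.2557574982, -9.1558561530, 20.642075974,
                -38.804430052, 93.626774077, -29.666905585])

_ETA_MAX = 0.74  # packing-fraction ceiling (close packing)
_CSTEP = 1e-200  # complex-step size


class ConvergenceError(RuntimeError):
    pass


class PhaseNotFoundError(RuntimeError):
    pass


@dataclass(frozen=True)
class PureComponentParams:
    """Pure-component PC-SAFT parameter record.

    m: segments per chain (non-integer allowed); sigma: segment diameter, A;
    eps_k: dispersion energy / k_B, K; epsAB_k: association energy / k_B, K;
    kappaAB: association volume; n_sites: number of association sites
    (2 = one donor + one acceptor); Mw: molar mass, g/mol.
    """

    name: str
    m: float
    sigma: float
    eps_k: float
    epsAB_k: float = 0.0
    kappaAB: float = 0.0
    n_sites: int = 0
    Mw: float = 0.0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError(f"{self.name}: m must be >= 1")
        if self.sigma <= 0:
            raise ValueError(f"{self.name}: sigma must be positive")
        if not (0.0 <= self.kappaAB < 1.0):
            raise ValueError(f"{self.name}: kappaAB must lie in [0, 1)")
        if self.epsAB_k < 0:
            raise ValueError(f"{self.name}: epsAB_k must be non-negative")


class BinaryInteractionSet:
    """Symmetric map of binary interaction parameters k_ij (default 0)."""

    def __init__(self, values: dict | None = None):
        self._k = {}
        for pair, v in (values or {}).items():
            self.set(pair[0], pair[1], v)

    def set(self, name_i: str, name_j: str, value: float):
        if abs(value) >= 1.0:
            raise ValueError(f"|k_ij| must be < 1, got {value} for {name_i}-{name_j}")
        self._k[frozenset((name_i, name_j))] = float(value)

    def get(self, name_i: str, name_j: str) -> float:
        return self._k.get(frozenset((name_i, name_j)), 0.0)


def combining_rules(i: PureComponentParams, j: PureComponentParams,
                    kij: float = 0.0) -> dict:
    """Berthelot-Lorentz cross parameters.

    sigma_ij = (sigma_i + sigma_j)/2;  eps_ij = sqrt(eps_i eps_j)(1 - k_ij).
    """
    return {
        "sigma_ij": 0.5 * (i.sigma + j.sigma),
        "eps_ij_k": np.sqrt(i.eps_k * j.eps_k) * (1.0 - kij),
    }


@dataclass(frozen=True)
class AssociationSolution:
    """Fraction of molecules not bonded at each site, plus strengths.

    ``X`` maps component name -> unbonded fraction (identical for the donor
    and acceptor site of a 2B component).  ``Delta`` is the component-pair
    association-strength matrix in A^3.
    """

    X: dict
    Delta: np.ndarray
    iterations: int
    residual: float


@dataclass(frozen=True)
class ResidualEnergies:
    a_hc: float
    a_disp: float
    a_assoc: float

    @property
    def a_res(self) -> float:
        return self.a_hc + self.a_disp + self.a_assoc


class Mixture:
    """A PC-SAFT mixture: components, k_ij and the association topology.

    ``assoc_pairs`` lists the component pairs (i, j) whose sites are allowed
    to hydrogen-bond; by default only the self-association of components
    carrying both sites and a non-zero kappaAB is switched on.  For the
    API/HPMC/water suspension the physically significant channel is
    water-water (stabilizer mole fractions are < 0.01 and the API does not
    self-associate), which is what the shipped data files enable.
    """

    def __init__(self, components, kij: BinaryInteractionSet | None = None,
                 assoc_pairs=None,
                 assoc_damping: float = 0.5, assoc_tol: float = 1e-12,
                 assoc_maxiter: int = 500):
        self.components = list(components)
        self.names = [c.name for c in self.components]
        self.kij = kij or BinaryInteractionSet()
        if assoc_pairs is None:
            assoc_pairs = {(c.name, c.name) for c in self.components
                           if c.n_sites >= 2 and c.kappaAB > 0 and c.epsAB_k > 0}
        self.assoc_pairs = {frozenset(p) for p in assoc_pairs}
        self.assoc_damping = assoc_damping
        self.assoc_tol = assoc_tol
        self.assoc_maxiter = assoc_maxiter

        self.m = np.array([c.m for c in self.components])
        self.sigma = np.array([c.sigma for c in self.components])
        self.eps_k = np.array([c.eps_k for c in self.components])
        n = len(self.components)
        self.sigma_ij = np.zeros((n, n))
        self.eps_ij_k = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                cr = combining_rules(self.components[a], self.components[b],
                                     self.kij.get(self.names[a], self.names[b]))
                self.sigma_ij[a, b] = cr["sigma_ij"]
                self.eps_ij_k[a, b] = cr["eps_ij_k"]

    # -- geometry ------------------------------------------------------------
    def d_T(self, T: float) -> np.ndarray:
        """Temperature-dependent segment diameters, A."""
        return self.sigma * (1.0 - 0.12 * np.exp(-3.0 * self.eps_k / T))

    def _zetas(self, rho_n, x, d):
        """Packing moments zeta_0..zeta_3 (rho_n in A^-3)."""
        return [np.pi / 6.0 * rho_n * np.sum(x * self.m * d ** k)
                for k in range(4)]

    def packing_fraction(self, T: float, rho_molar, x) -> float:
        rho_n = rho_molar * N_AVOGADRO * 1e-30
        d = self.d_T(T)
        return np.pi / 6.0 * rho_n * np.sum(np.asarray(x) * self.m * d ** 3)

    def rho_from_eta(self, T: float, eta: float, x) -> float:
        """Molar density (mol/m^3) at a given packing fraction."""
        d = self.d_T(T)
        s = np.pi / 6.0 * np.sum(np.asarray(x) * self.m * d ** 3)
        return eta / s / (N_AVOGADRO * 1e-30)

    def _g_hs(self, zetas, d):
        """Hard-sphere radial distribution at contact, pairwise matrix."""
        z2, z3 = zetas[2], zetas[3]
        dd = np.add.outer(d, d)
        w = np.multiply.outer(d, d) / dd
        return (1.0 / (1.0 - z3)
                + w * 3.0 * z2 / (1.0 - z3) ** 2
                + w ** 2 * 2.0 * z2 ** 2 / (1.0 - z3) ** 3)

    # -- association ----------------------------------------------------------
    def _delta_matrix(self, T, zetas, d):
        """Association strengths Delta_ij (A^3) for the enabled pairs."""
        n = len(self.components)
        g = self._g_hs(zetas, d)
        Delta = np.zeros((n, n), dtype=g.dtype)
        for a in range(n):
            for b in range(n):
                if frozenset((self.names[a], self.names[b])) not in self.assoc_pairs:
                    continue
                ca, cb = self.components[a], self.components[b]
                if ca.kappaAB <= 0 or cb.kappaAB <= 0:
                    continue
                # Wolbach-Sandler cross rules (reduce to pure values on the diagonal)
                epsAB = 0.5 * (ca.epsAB_k + cb.epsAB_k)
                kapAB = np.sqrt(ca.kappaAB * cb.kappaAB) * (
                    np.sqrt(ca.sigma * cb.sigma) / self.sigma_ij[a, b]) ** 3
                d_ab = 0.5 * (d[a] + d[b])
                Delta[a, b] = d_ab ** 3 * g[a, b] * kapAB * (np.exp(epsAB / T) - 1.0)
        return Delta

    def association_fractions(self, T, rho_molar, x) -> AssociationSolution:
        """Solve the unbonded site fractions X for the 2B topology.

        X_i = 1/(1 + sum_j rho_j X_j Delta_ij), with rho_j the molecular
        number density of component j.  Solved by damped successive
        substitution; the single-associator case uses the closed form
        X = (-1 + sqrt(1 + 4 rho Delta))/(2 rho Delta).
        """
        x = np.asarray(x)
        rho_n = rho_molar * N_AVOGADRO * 1e-30
        d = self.d_T(T)
        zetas = self._zetas(rho_n, x, d)
        Delta = self._delta_matrix(T, zetas, d)
        rho_i = rho_n * x
        active = [a for a in range(len(x)) if np.any(np.abs(Delta[a]) > 0)]
        X = np.ones(len(x), dtype=np.result_type(Delta, rho_i))
        if not active:
            return AssociationSolution(
                dict(zip(self.names, X)), Delta, 0, 0.0)
        if len(active) == 1:
            a = active[0]
            rd = rho_i[a] * Delta[a, a]
            X[a] = 1.0 if np.abs(rd) < 1e-300 else \
                (-1.0 + np.sqrt(1.0 + 4.0 * rd)) / (2.0 * rd)
            return AssociationSolution(dict(zip(self.names, X)), Delta, 0, 0.0)
        lam = self.assoc_damping
        res = np.inf
        for it in range(self.assoc_maxiter):
            Xnew = 1.0 / (1.0 + (Delta[np.ix_(active, active)]
                                 @ (rho_i[active] * X[active])))
            res = float(np.max(np.abs(Xnew - X[active])))
            X[active] = lam * Xnew + (1.0 - lam) * X[active]
            if res < self.assoc_tol:
                return AssociationSolution(dict(zip(self.names, X)), Delta, it + 1, res)
        raise ConvergenceError(
            f"association solver did not converge: residual {res:.3e} after "
            f"{self.assoc_maxiter} iterations")

    # -- Helmholtz terms -------------------------------------------------------
    def residual_helmholtz(self, T, rho_molar, x) -> ResidualEnergies:
        """Reduced residual Helmholtz energy per mole, a_res = a_hc+a_disp+a_assoc.

        Accepts complex ``rho_molar``/``x`` for complex-step differentiation.
        """
        x = np.asarray(x)
        rho_n = rho_molar * N_AVOGADRO * 1e-30
        d = self.d_T(T)
        z0, z1, z2, z3 = self._zetas(rho_n, x, d)
        if np.real(z3) >= _ETA_MAX:
            raise ValueError(
                f"packing fraction {np.real(z3):.3f} >= {_ETA_MAX}: density out of range")
        mbar = np.sum(x * self.m)

        # hard sphere + chain
        one = 1.0 - z3
        a_hs = (3.0 * z1 * z2 / one
                + z2 ** 3 / (z3 * one ** 2)
                + (z2 ** 3 / z3 ** 2 - z0) * np.log(one)) / z0
        g_ii = np.diag(self._g_hs((z0, z1, z2, z3), d))
        a_hc = mbar * a_hs - np.sum(x * (self.m - 1.0) * np.log(g_ii))

        # dispersion
        eta = z3
        am = _A0 + (mbar - 1.0) / mbar * _A1 + (mbar - 1.0) * (mbar - 2.0) / mbar ** 2 * _A2
        bm = _B0 + (mbar - 1.0) / mbar * _B1 + (mbar - 1.0) * (mbar - 2.0) / mbar ** 2 * _B2
        powers = eta ** np.arange(7)
        I1 = np.sum(am * powers)
        I2 = np.sum(bm * powers)
        C1 = 1.0 / (1.0
                    + mbar * (8.0 * eta - 2.0 * eta ** 2) / one ** 4
                    + (1.0 - mbar) * (20.0 * eta - 27.0 * eta ** 2
                                      + 12.0 * eta ** 3 - 2.0 * eta ** 4)
                    / (one * (2.0 - eta)) ** 2)
        xm = x * self.m
        e_T = self.eps_ij_k / T
        m2es3 = np.einsum("i,j,ij,ij->", xm, xm, e_T, self.sigma_ij ** 3)
        m2e2s3 = np.einsum("i,j,ij,ij->", xm, xm, e_T ** 2, self.sigma_ij ** 3)
        a_disp = (-2.0 * np.pi * rho_n * I1 * m2es3
                  - np.pi * rho_n * mbar * C1 * I2 * m2e2s3)

        # association (2B per component: M_i sites, symmetric donor/acceptor)
        a_assoc = 0.0 * a_hc
        if self.assoc_pairs:
            sol = self.association_fractions(T, rho_molar, x)
            for a, c in enumerate(self.components):
                if c.n_sites and np.any(np.abs(sol.Delta[a]) > 0):
                    Xa = sol.X[c.name]
                    a_assoc = a_assoc + x[a] * c.n_sites * (
                        np.log(Xa) - Xa / 2.0 + 0.5)
        return ResidualEnergies(a_hc=a_hc, a_disp=a_disp, a_assoc=a_assoc)

    # -- derivative machinery ---------------------------------------------------
    def _a_res(self, T, rho, x):
        r = self.residual_helmholtz(T, rho, x)
        return r.a_hc + r.a_disp + r.a_assoc

    def compressibility(self, T, rho_molar, x) -> float:
        """Z = 1 + rho d(a_res)/d(rho), density derivative by complex step."""
        da = np.imag(self._a_res(T, rho_molar + 1j * _CSTEP * rho_molar, x)) / (
            _CSTEP * rho_molar)
        return 1.0 + rho_molar * da

    def pressure(self, T, rho_molar, x) -> float:
        """P(T, rho, x) in Pa."""
        return self.compressibility(T, rho_molar, x) * rho_molar * R_GAS * T

    def density_solve(self, T, P, x, phase: str = "liquid") -> float:
        """Molar density root of P(rho) = P on the requested phase branch.

        Roots are located by scanning the packing fraction over
        (1e-12, 0.7), bracketing sign changes of P(eta) - P and polishing
        with Brent's method; the liquid branch is the densest root, the
        vapor branch the least dense.
        """
        if P <= 0:
            raise ValueError("P must be positive")
        x = np.asarray(x, dtype=float)
        etas = np.concatenate([
            np.geomspace(1e-12, 1e-2, 25), np.linspace(0.012, 0.70, 90)])
        rhos = np.array([self.rho_from_eta(T, e, x) for e in etas])
        f = np.array([self.pressure(T, r, x) - P for r in rhos])
        roots = []
        for i in range(len(etas) - 1):
            if f[i] == 0.0:
                roots.append(rhos[i])
            elif f[i] * f[i + 1] < 0:
                r = brentq(lambda rho: self.pressure(T, rho, x) - P,
                           rhos[i], rhos[i + 1], xtol=1e-12, rtol=1e-14)
                roots.append(r)
        if not roots:
            raise PhaseNotFoundError(
                f"no density root for T={T} K, P={P} Pa, phase={phase}")
        return max(roots) if phase == "liquid" else min(roots)

    def ln_phi(self, T, P=None, x=None, rho_molar=None, phase: str = "liquid"):
        """Log fugacity coefficients ln(phi_i).

        ln phi_i = d(n a_res)/d n_i |_(T,V) - ln Z, with the mole-number
        derivative taken by complex step at fixed total volume.
        """
        x = np.asarray(x, dtype=float)
        if rho_molar is None:
            rho_molar = self.density_solve(T, P, x, phase)
        Z = self.compressibility(T, rho_molar, x)
        n = x.astype(complex)  # basis: 1 mol total, V = 1/rho_molar
        V = 1.0 / rho_molar
        out = np.empty(len(x))
        for i in range(len(x)):
            ni = n.copy()
            ni[i] += 1j * _CSTEP
            ntot = np.sum(ni)
            F = ntot * self._a_res(T, ntot / V, ni / ntot)
            out[i] = np.imag(F) / _CSTEP
        return out - np.log(Z)

    def fugacity_activity(self, T, P, x) -> dict:
        """Fugacity coefficients phi_i and activity coefficients gamma_i.

        gamma_i = phi_i / phi_i^0 with phi_i^0 the pure-liquid fugacity
        coefficient of component i at the same T and P.
        """
        x = np.asarray(x, dtype=float)
        lnphi = self.ln_phi(T, P, x)
        lnphi0 = np.empty(len(x))
        for i, c in enumerate(self.components):
            pure = Mixture([c], assoc_pairs=self.assoc_pairs & {frozenset((c.name,))},
                           assoc_damping=self.assoc_damping,
                           assoc_tol=self.assoc_tol, assoc_maxiter=self.assoc_maxiter)
            lnphi0[i] = pure.ln_phi(T, P, np.array([1.0]), phase="liquid")[0]
        phi = np.exp(lnphi)
        gamma = np.exp(lnphi - lnphi0)
        return {"phi": dict(zip(self.names, phi)),
                "gamma": dict(zip(self.names, gamma)),
                "lnphi": dict(zip(self.names, lnphi))}
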