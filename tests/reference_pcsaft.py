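"""Independent scalar PC-SAFT reference for cross-checking the package.

This is a deliberately separate, loop-based transcription of the
perturbed-chain SAFT equations (hard-chain + dispersion + 2B association),
kept free of any code from ``nanosusp``: its own universal-constant table,
its own packing algebra, its own pressure (finite differences of its own
Helmholtz energy) and its own bisection density solve.  It exists only as a
test oracle; do not use it for production work.
"""

import math

from scipy.optimize import brentq

KB = 1.380649e-23
NAV = 6.02214076e23

# universal model constants, (a0, a1, a2) and (b0, b1, b2) per order 0..6
APC = [
    (0.9105631445, -0.3084016918, -0.0906148351),
    (0.6361281449, 0.1860531159, 0.4527842806),
    (2.6861347891, -2.5030047259, 0.5962700728),
    (-26.547362491, 21.419793629, -1.7241829131),
    (97.759208784, -65.255885330, -4.1302112531),
    (-159.59154087, 83.318680481, 13.776631870),
    (91.297774084, -33.746922930, -8.6728470368),
]
BPC = [
    (0.7240946941, -0.5755498075, 0.0976883116),
    (2.2382791861, 0.6995095521, -0.2557574982),
    (-4.0025849485, 3.8925673390, -9.1558561530),
    (-21.003576815, -17.215471648, 20.642075974),
    (26.855641363, 192.67226447, -38.804430052),
    (206.55133841, -161.82646165, 93.626774077),
    (-355.60235612, -165.20769346, -29.666905585),
]


def a_res_ref(T, rho_molar, x, comps, kij=None):
    """Reduced residual Helmholtz energy (a_hc, a_disp, a_assoc).

    ``comps`` is a list of dicts with keys m, sigma, eps_k and optionally
    epsAB_k, kappaAB, n_sites (at most one self-associating component).
    ``kij`` an optional dict {(i,j): value} on indices.
    """
    n = len(comps)
    kij = kij or {}
    rho = rho_molar * NAV * 1e-30  # A^-3
    d = [c["sigma"] * (1.0 - 0.12 * math.exp(-3.0 * c["eps_k"] / T)) for c in comps]
    z = [math.pi / 6.0 * rho * sum(x[i] * comps[i]["m"] * d[i] ** k for i in range(n))
         for k in range(4)]
    z0, z1, z2, z3 = z
    mbar = sum(x[i] * comps[i]["m"] for i in range(n))

    # hard sphere / chain
    omz = 1.0 - z3
    a_hs = (3.0 * z1 * z2 / omz + z2 ** 3 / (z3 * omz * omz)
            + (z2 ** 3 / (z3 * z3) - z0) * math.log(omz)) / z0
    a_hc = mbar * a_hs
    for i in range(n):
        w = d[i] * d[i] / (d[i] + d[i])
        gii = (1.0 / omz + w * 3.0 * z2 / omz ** 2 + w * w * 2.0 * z2 ** 2 / omz ** 3)
        a_hc -= x[i] * (comps[i]["m"] - 1.0) * math.log(gii)

    # dispersion
    eta = z3
    i1 = i2 = 0.0
    for j in range(7):
        aj = APC[j][0] + (mbar - 1.0) / mbar * APC[j][1] \
            + (mbar - 1.0) * (mbar - 2.0) / mbar ** 2 * APC[j][2]
        bj = BPC[j][0] + (mbar - 1.0) / mbar * BPC[j][1] \
            + (mbar - 1.0) * (mbar - 2.0) / mbar ** 2 * BPC[j][2]
        i1 += aj * eta ** j
        i2 += bj * eta ** j
    c1 = 1.0 / (1.0 + mbar * (8.0 * eta - 2.0 * eta ** 2) / omz ** 4
                + (1.0 - mbar) * (20.0 * eta - 27.0 * eta ** 2 + 12.0 * eta ** 3
                                  - 2.0 * eta ** 4) / (omz * (2.0 - eta)) ** 2)
    m2es3 = m2e2s3 = 0.0
    for i in range(n):
        for j in range(n):
            sij = 0.5 * (comps[i]["sigma"] + comps[j]["sigma"])
            eij = math.sqrt(comps[i]["eps_k"] * comps[j]["eps_k"]) \
                * (1.0 - kij.get((i, j), kij.get((j, i), 0.0)))
            common = x[i] * x[j] * comps[i]["m"] * comps[j]["m"] * sij ** 3
            m2es3 += common * eij / T
            m2e2s3 += common * (eij / T) ** 2
    a_disp = (-2.0 * math.pi * rho * i1 * m2es3
              - math.pi * rho * mbar * c1 * i2 * m2e2s3)

    # association: single self-associating 2B component
    a_assoc = 0.0
    for i, c in enumerate(comps):
        if c.get("kappaAB", 0.0) > 0 and c.get("epsAB_k", 0.0) > 0 and x[i] > 0:
            w = d[i] * d[i] / (d[i] + d[i])
            gii = (1.0 / omz + w * 3.0 * z2 / omz ** 2
                   + w * w * 2.0 * z2 ** 2 / omz ** 3)
            delta = d[i] ** 3 * gii * c["kappaAB"] * (math.exp(c["epsAB_k"] / T) - 1.0)
            rd = rho * x[i] * delta
            X = 1.0 if rd == 0 else (-1.0 + math.sqrt(1.0 + 4.0 * rd)) / (2.0 * rd)
            a_assoc += x[i] * c.get("n_sites", 2) * (math.log(X) - X / 2.0 + 0.5)
    return a_hc, a_disp, a_assoc


def pressure_ref(T, rho_molar, x, comps, kij=None):
    """P in Pa via a 5-point finite-difference compressibility."""
    h = rho_molar * 1e-6

    def a(r):
        return sum(a_res_ref(T, r, x, comps, kij))

    dadrho = (a(rho_molar - 2 * h) - 8 * a(rho_molar - h)
              + 8 * a(rho_molar + h) - a(rho_molar + 2 * h)) / (12 * h)
    Z = 1.0 + rho_molar * dadrho
    return Z * rho_molar * KB * NAV * T


def liquid_density_ref(T, P, x, comps, kij=None):
    """Densest root of P(rho) = P by bracketed bisection on a grid."""
    n = len(comps)
    d3 = [ (c["sigma"] * (1.0 - 0.12 * math.exp(-3.0 * c["eps_k"] / T))) ** 3
           for c in comps ]
    s = math.pi / 6.0 * sum(x[i] * comps[i]["m"] * d3[i] for i in range(n))
    rho_eta = lambda eta: eta / s / (NAV * 1e-30)
    etas = [1e-10 * 10 ** (k * 0.5) for k in range(10)] + \
           [0.01 + 0.69 * k / 120.0 for k in range(121)]
    best = None
    prev_eta, prev_f = None, None
    for eta in etas:
        f = pressure_ref(T, rho_eta(eta), x, comps, kij) - P
        if prev_f is not None and prev_f * f < 0:
            best = brentq(lambda e: pressure_ref(T, rho_eta(e), x, comps, kij) - P,
                          prev_eta, eta, xtol=1e-13)
        prev_eta, prev_f = eta, f
    if best is None:
        raise RuntimeError("no liquid root found")
    return rho_eta(best)
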