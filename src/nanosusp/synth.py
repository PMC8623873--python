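"""Synthetic stiffness tensors and test-case generators.

All generators are deterministic under a seed and produce tensors that
satisfy the mechanical-stability invariants, so they can stand in for
force-field-derived stiffness matrices in tests and demos.
"""

from __future__ import annotations

import numpy as np

from .elastic import StiffnessTensor

__all__ = [
    "isotropic_stiffness",
    "cubic_stiffness",
    "orthorhombic_stiffness",
    "random_spd_stiffness",
    "generate_stiffness",
]


def isotropic_stiffness(K: float, G: float) -> StiffnessTensor:
    """Isotropic tensor from bulk and shear moduli (GPa)."""
    c11 = K + 4.0 * G / 3.0
    c12 = K - 2.0 * G / 3.0
    C = np.zeros((6, 6))
    C[:3, :3] = c12
    np.fill_diagonal(C[:3, :3], c11)
    C[3, 3] = C[4, 4] = C[5, 5] = G
    return StiffnessTensor(C)


def cubic_stiffness(c11: float, c12: float, c44: float) -> StiffnessTensor:
    C = np.zeros((6, 6))
    C[:3, :3] = c12
    np.fill_diagonal(C[:3, :3], c11)
    C[3, 3] = C[4, 4] = C[5, 5] = c44
    return StiffnessTensor(C)


def orthorhombic_stiffness(diag, offdiag) -> StiffnessTensor:
    """Orthorhombic tensor from 6 diagonal (C11..C66) and 3 off-diagonal
    (C12, C13, C23) constants, GPa."""
    C = np.zeros((6, 6))
    np.fill_diagonal(C, diag)
    C[0, 1] = C[1, 0] = offdiag[0]
    C[0, 2] = C[2, 0] = offdiag[1]
    C[1, 2] = C[2, 1] = offdiag[2]
    return StiffnessTensor(C)


def random_spd_stiffness(
    rng: np.random.Generator | int, eig_range: tuple = (0.5, 50.0)
) -> StiffnessTensor:
    """Random triclinic SPD tensor: symmetric Gaussian matrix with its
    eigenvalues clipped into ``eig_range`` (GPa)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    A = rng.normal(size=(6, 6))
    A = 0.5 * (A + A.T)
    w, V = np.linalg.eigh(A)
    lo, hi = eig_range
    w = lo + (hi - lo) * (w - w.min()) / (w.max() - w.min())
    return StiffnessTensor(V @ np.diag(w) @ V.T)


def generate_stiffness(symmetry: str, seed: int | None = None, **params) -> StiffnessTensor:
    """Dispatch by symmetry class: isotropic, cubic, orthorhombic, random_spd."""
    if symmetry == "isotropic":
        return isotropic_stiffness(params["K"], params["G"])
    if symmetry == "cubic":
        return cubic_stiffness(params["c11"], params["c12"], params["c44"])
    if symmetry == "orthorhombic":
        return orthorhombic_stiffness(params["diag"], params["offdiag"])
    if symmetry == "random_spd":
        return random_spd_stiffness(np.random.default_rng(seed),
                                    params.get("eig_range", (0.5, 50.0)))
    raise ValueError(f"unknown symmetry class {symmetry!r}")
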