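"""Chemically-weighted anisotropic elastic network: Hessian, modes, B-factors.

The protein is a network of Cα beads joined by harmonic springs. Force
constants follow contact chemistry: covalent neighbours and disulfides get
the full spring constant γ, hydrogen bonds / salt bridges 0.1 γ, and all
other pairs within the cutoff r_c a weak 0.01 γ. Units: coordinates in Å,
eigenvalues in γ/Å² with γ = 1; the absolute B-factor scale is arbitrary
(only rank correlations and normalized vectors are consumed downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.stats import spearmanr

from .structio import CaStructure, ContactGraph, detect_contacts

#: force constant per contact class, in units of γ
FORCE_CONSTANTS = {
    "covalent": 1.0,
    "disulfide": 1.0,
    "hbond_salt": 0.1,
    "generic": 0.01,
}

#: relative eigenvalue threshold below which a mode counts as null
NULL_MODE_RTOL = 1e-8

B_PREFACTOR = 8.0 * np.pi**2 / 3.0  # Eqs for B_i, k_B T = 1


class EnmError(ValueError):
    """Raised for ill-posed networks (disconnected, coincident beads ...)."""


@dataclass
class EnmModel:
    structure: CaStructure
    springs: list[tuple[int, int, float]]  # (i, j, k_ij in γ units)
    gamma: float
    r_c: float
    hessian: np.ndarray  # (3N, 3N)


@dataclass
class ModeSet:
    """Eigen-decomposition of the Hessian, ascending eigenvalues.

    ``internal`` indexes the 3N−6 non-null modes into the full arrays.
    """

    eigenvalues: np.ndarray  # (3N,)
    eigenvectors: np.ndarray  # (3N, 3N), orthonormal columns
    n_zero: int

    @property
    def n_residues(self) -> int:
        return self.eigenvectors.shape[0] // 3

    @property
    def internal(self) -> np.ndarray:
        return np.arange(self.n_zero, len(self.eigenvalues))

    @property
    def internal_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero:]

    @property
    def internal_modes(self) -> np.ndarray:
        """(3N, 3N−n_zero) matrix of internal-mode columns."""
        return self.eigenvectors[:, self.n_zero:]


@dataclass
class BFactorProfile:
    values: np.ndarray  # per residue, arbitrary units ∝ Å²


def assign_force_constants(
    contacts: ContactGraph, gamma: float = 1.0
) -> list[tuple[int, int, float]]:
    """Map typed contacts to springs: γ for covalent/disulfide, 0.1 γ for
    hbond-or-saltbridge, 0.01 γ for generic."""
    return [
        (i, j, gamma * FORCE_CONSTANTS[cls])
        for (i, j), cls in sorted(contacts.edges.items())
    ]


def build_hessian(
    structure: CaStructure,
    springs: list[tuple[int, int, float]],
    gamma: float = 1.0,
    r_c: float = 10.0,
) -> EnmModel:
    """Assemble the 3N×3N anisotropic-network Hessian.

    Each spring contributes the block k_ij · (r̂_ij r̂_ij^T) with the usual
    sign structure (+ on the two diagonal blocks, − on the off-diagonals),
    so every row-block sums to zero (translational invariance).
    """
    coords = structure.coords
    n = len(structure)
    H = np.zeros((3 * n, 3 * n))
    for i, j, k in springs:
        rij = coords[j] - coords[i]
        d = np.linalg.norm(rij)
        if d < 1e-6:
            raise EnmError(f"coincident Cα positions on spring ({i}, {j})")
        u = rij / d
        block = k * np.outer(u, u)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[si, si] += block
        H[sj, sj] += block
        H[si, sj] -= block
        H[sj, si] -= block
    return EnmModel(structure=structure, springs=list(springs),
                    gamma=gamma, r_c=r_c, hessian=H)


def _connected_components(n: int, springs) -> list[set[int]]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, k in springs:
        if k > 0:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
    comps: dict[int, set[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())


def diagonalize(model: EnmModel, null_rtol: float = NULL_MODE_RTOL) -> ModeSet:
    """Eigen-decompose the Hessian; identify null modes by λ < rtol·max λ.

    A connected, non-collinear bead network has exactly 6 null modes; more
    indicates a disconnected network and raises, naming the components.
    """
    w, v = scipy.linalg.eigh(model.hessian)
    tol = null_rtol * max(w[-1], 1.0)
    n_zero = int(np.sum(w < tol))
    if n_zero > 6:
        comps = _connected_components(len(model.structure), model.springs)
        raise EnmError(
            f"{n_zero} null modes: network disconnected into "
            f"{len(comps)} components with sizes {sorted(map(len, comps))}"
        )
    w = np.clip(w, 0.0, None)
    return ModeSet(eigenvalues=w, eigenvectors=v, n_zero=n_zero)


def theoretical_bfactors(modes: ModeSet) -> BFactorProfile:
    """Per-residue theoretical B-factor from the internal modes.

    B_i = (8π²/3) · 3 k_B T · Σ_k λ_k⁻¹ (q_k q_k^T)_ii, summed over the
    three coordinates of residue i (k_B T = 1, arbitrary overall scale).
    Equals the diagonal of the Hessian pseudo-inverse times the prefactor.
    """
    lam = modes.internal_eigenvalues
    if np.any(lam <= 0):
        raise EnmError("zero eigenvalue among internal modes")
    Q = modes.internal_modes  # (3N, m)
    msf3 = (Q**2 / lam[None, :]).sum(axis=1)  # per-coordinate Σ λ⁻¹ q²
    per_res = msf3.reshape(-1, 3).sum(axis=1)
    return BFactorProfile(values=B_PREFACTOR * 3.0 * per_res)


def build_enm(
    structure: CaStructure,
    r_c: float = 10.0,
    gamma: float = 1.0,
    full_atom_path: str | None = None,
    contacts: ContactGraph | None = None,
) -> tuple[EnmModel, ModeSet]:
    """Convenience: contacts → springs → Hessian → modes."""
    if contacts is None:
        contacts = detect_contacts(structure, full_atom_path, r_c=r_c)
    springs = assign_force_constants(contacts, gamma=gamma)
    model = build_hessian(structure, springs, gamma=gamma, r_c=r_c)
    return model, diagonalize(model)


def calibrate_cutoff(
    structure: CaStructure,
    experimental_b: np.ndarray,
    full_atom_path: str | None = None,
    grid: np.ndarray | None = None,
) -> tuple[float, float, list[tuple[float, float]]]:
    """Pick r_c on a [7, 20] Å grid (0.5 Å step) maximizing the Spearman
    correlation between theoretical and experimental B-factors.

    Ties break toward smaller r_c (sparser network). Returns
    (r_c*, spearman*, full curve).
    """
    experimental_b = np.asarray(experimental_b, dtype=float)
    if np.ptp(experimental_b) == 0:
        raise EnmError("constant experimental B-factors: correlation undefined")
    if grid is None:
        grid = np.arange(7.0, 20.0 + 1e-9, 0.5)
    curve = []
    for r_c in grid:
        try:
            _, modes = build_enm(structure, r_c=float(r_c),
                                 full_atom_path=full_atom_path)
            theo = theoretical_bfactors(modes).values
            rho = float(spearmanr(theo, experimental_b).statistic)
        except EnmError:
            rho = np.nan  # disconnected at small r_c: skip grid point
        curve.append((float(r_c), rho))
    valid = [(r, s) for r, s in curve if np.isfinite(s)]
    if not valid:
        raise EnmError("no cutoff on the grid yields a connected network")
    best_r, best_s = max(valid, key=lambda rs: (rs[1], -rs[0]))
    return best_r, best_s, curve


def write_calibration_curve(curve, path: str) -> None:
    import pandas as pd

    pd.DataFrame(curve, columns=["r_c", "spearman"]).to_csv(
        path, sep="\t", index=False, float_format="%.4f")


def write_mode_table(modes: ModeSet, path: str) -> None:
    """Plain-text mode table: 1-based internal mode index, eigenvalue,
    collectivity."""
    import pandas as pd

    from .modespace import collectivity

    rows = []
    Q = modes.internal_modes
    for k in range(Q.shape[1]):
        rows.append((k + 1, modes.internal_eigenvalues[k],
                     collectivity(Q[:, k])))
    pd.DataFrame(rows, columns=["mode", "eigenvalue", "collectivity"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")
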