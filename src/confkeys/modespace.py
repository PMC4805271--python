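"""Conformational-change vector, mode expansions, participation, subspaces.

The unbound→bound displacement is expressed on the ligand-free normal-mode
basis. Its participation number P (inverse fourth moment of the expansion
coefficients) gives the effective number of modes involved; the ceil(P)
modes with the largest squared coefficients form the binding subspace S.
The same machinery applied to the B-factor profile yields S_B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .enm_core import BFactorProfile, ModeSet
from .structio import ConformerPair

DEFAULT_W = 0.01  # Gaussian B-factor weighting scale


class ModeSpaceError(ValueError):
    pass


@dataclass
class DisplacementVector:
    v: np.ndarray  # unit 3N vector
    w: float
    source: str  # "conformational-change" | "bfactor"


@dataclass
class ModeExpansion:
    """Expansion of a unit 3N vector on internal modes.

    ``coefficients`` are renormalized to unit length within the internal-mode
    span; ``discarded_fraction`` is the squared norm lost to the null-mode
    span before renormalization.
    """

    coefficients: np.ndarray  # c_k per internal mode, unit norm
    participation: float  # P = 1 / Σ c_k⁴
    subspace_size: int  # M = ceil(P)
    ranking: np.ndarray  # internal-mode positions, descending c_k²
    discarded_fraction: float

    @property
    def P(self) -> float:
        return self.participation


@dataclass
class ModeSubspace:
    mode_indices: np.ndarray  # positions into the internal-mode ordering
    basis: np.ndarray  # (3N, M) orthonormal columns
    label: str  # "S" | "S_B" | "S_i"

    @property
    def M(self) -> int:
        return self.basis.shape[1]


def weighted_difference(
    pair: ConformerPair,
    bfactors_free: np.ndarray,
    bfactors_bound: np.ndarray,
    w: float = DEFAULT_W,
) -> DisplacementVector:
    """Unit displacement vector with Gaussian B-factor down-weighting.

    v_i ∝ (y_i − x_i) · exp(−(B_i^lf + B_i^lb) · w); flexible (high-B)
    regions such as loops and termini are suppressed so the vector tracks
    the binding-related distortion. Residue weights act on all three
    coordinates of a residue.
    """
    fi, bi = pair.mapping[:, 0], pair.mapping[:, 1]
    diff = pair.bound.coords[bi] - pair.free.coords[fi]  # (M, 3)
    bsum = np.asarray(bfactors_free)[fi] + np.asarray(bfactors_bound)[bi]
    weighted = diff * np.exp(-bsum * w)[:, None]
    flat = weighted.ravel()
    norm = np.linalg.norm(flat)
    if norm < 1e-12:
        raise ModeSpaceError("no conformational change between conformers")
    return DisplacementVector(v=flat / norm, w=w, source="conformational-change")


def expand_on_modes(v: DisplacementVector | np.ndarray, modes: ModeSet) -> ModeExpansion:
    """Expand a unit vector on the internal modes; P = 1/Σ c_k⁴.

    The coefficients are renormalized over the internal-mode span (a
    residual rigid-body component survives superposition); the discarded
    fraction is recorded. Ranking is by descending c_k², ties by ascending
    mode index.
    """
    vec = v.v if isinstance(v, DisplacementVector) else np.asarray(v, dtype=float)
    if vec.shape[0] != modes.eigenvectors.shape[0]:
        raise ModeSpaceError("dimension mismatch between vector and modes")
    c = modes.internal_modes.T @ vec
    total = float(c @ c)
    if total < 1e-6:
        raise ModeSpaceError("vector lies in the null-mode span")
    discarded = max(0.0, 1.0 - total)
    c = c / np.sqrt(total)
    P = float(1.0 / np.sum(c**4))
    order = np.lexsort((np.arange(len(c)), -(c**2)))
    return ModeExpansion(
        coefficients=c,
        participation=P,
        subspace_size=math.ceil(P - 1e-9),
        ranking=order,
        discarded_fraction=discarded,
    )


def bfactor_expansion(bfactors: BFactorProfile | np.ndarray, modes: ModeSet) -> ModeExpansion:
    """Expand the flexibility profile on the modes (yields b_k, P_B, S_B).

    The per-residue B-factor is replicated over the residue's three
    coordinates, unit-normalized, then expanded like any displacement.
    """
    b = bfactors.values if isinstance(bfactors, BFactorProfile) else np.asarray(bfactors, float)
    if np.allclose(b, 0):
        raise ModeSpaceError("all-zero B-factor profile")
    vec = np.repeat(b, 3).astype(float)
    vec /= np.linalg.norm(vec)
    exp = expand_on_modes(vec, modes)
    return exp


def select_subspace(
    expansion: ModeExpansion, modes: ModeSet, label: str = "S"
) -> ModeSubspace:
    """The M = ceil(P) modes with largest squared coefficients (ties →
    ascending mode index), assembled into an orthonormal basis."""
    sel = np.sort(expansion.ranking[: expansion.subspace_size])
    basis = modes.internal_modes[:, sel]
    return ModeSubspace(mode_indices=sel, basis=basis, label=label)


def collectivity(mode: np.ndarray, n_residues: int | None = None) -> float:
    """Degree of collectivity κ ∈ [1/N, 1] of a normalized 3N mode vector.

    κ = (1/N)·exp(−Σ_i r_i² ln r_i²) with r_i² the summed squared
    components of residue i; uniform residue amplitudes give 1, a
    single-residue mode gives 1/N (0·ln 0 := 0).
    """
    mode = np.asarray(mode, dtype=float)
    n = n_residues if n_residues is not None else mode.shape[0] // 3
    r2 = (mode.reshape(-1, 3) ** 2).sum(axis=1)
    s = r2.sum()
    if s <= 0:
        raise ModeSpaceError("zero mode vector")
    r2 = r2 / s
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(r2 > 0, r2 * np.log(r2), 0.0)
    return float(np.exp(-terms.sum()) / n)


def write_subspace_report(
    expansion: ModeExpansion, modes: ModeSet, path: str
) -> None:
    """Subspace TSV: 1-based mode index, eigenvalue, c_k², cumulative Σc²,
    collectivity; rows in ranked order."""
    import pandas as pd

    rows = []
    cum = 0.0
    Q = modes.internal_modes
    for pos in expansion.ranking:
        c2 = float(expansion.coefficients[pos] ** 2)
        cum += c2
        rows.append((int(pos) + 1, float(modes.internal_eigenvalues[pos]),
                     c2, cum, collectivity(Q[:, pos])))
    pd.DataFrame(
        rows, columns=["mode", "eigenvalue", "c2", "cum_c2", "collectivity"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
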