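"""Residue-wise spring perturbation, mode re-matching, Gramian scoring.

A point mutation at residue i is simulated by scaling every spring incident
to i by (1 + δγ) and re-diagonalizing. Perturbed modes are put in one-to-one
correspondence with the unperturbed ones by maximizing the summed squared
overlaps (a linear assignment problem), the image of the binding subspace S
is collected, and the two subspaces are compared through the eigenvalues of
the Gramian of projections: ζ = Σλ(G)/M ∈ [0, 1]. Residues whose
perturbation most degrades ζ (lowest ZscoreS) are the key positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .enm_core import EnmModel, ModeSet, build_hessian, diagonalize
from .modespace import ModeSubspace
from .structio import CaStructure

DEFAULT_DELTA = 0.05
DEFAULT_KEY_FRACTION = 0.05
DEFAULT_NEIGHBOR_RADIUS = 7.0  # Å


class PerturbScanError(ValueError):
    pass


@dataclass
class ScoreProfile:
    """Per-residue perturbation-impact scores."""

    zeta_plus: np.ndarray
    zeta_minus: np.ndarray
    zeta_mean: np.ndarray
    zscore: np.ndarray  # ZscoreS, mean 0 / sd 1
    zscore_averaged: np.ndarray  # 7 Å neighbor-averaged ZscoreS

    def __len__(self) -> int:
        return len(self.zeta_mean)


@dataclass
class KeyPositionSet:
    indices: np.ndarray  # 0-based residue indices, ascending
    fraction: float
    count: int

    def __contains__(self, i: int) -> bool:
        return i in set(self.indices.tolist())


def perturb_residue(model: EnmModel, i: int, delta: float) -> EnmModel:
    """Scale every spring incident to residue i by (1 + δγ); rebuild H.

    The perturbation is multiplicative so that the spring-class ratios and
    positive semi-definiteness are preserved for any |δγ| ≤ 0.5.
    """
    if abs(delta) > 0.5:
        raise PerturbScanError(f"|δγ| = {abs(delta)} exceeds 0.5")
    incident = [s for s in model.springs if i in s[:2]]
    if not incident:
        raise PerturbScanError(f"residue {i} has no springs")
    springs = [
        (a, b, k * (1.0 + delta)) if i in (a, b) else (a, b, k)
        for a, b, k in model.springs
    ]
    return build_hessian(model.structure, springs, gamma=model.gamma,
                         r_c=model.r_c)


def match_modes(unperturbed: ModeSet, perturbed: ModeSet) -> np.ndarray:
    """One-to-one mode correspondence maximizing Σ O_kk'².

    O_kk' = q_k · q^i_k' over internal modes; solved as a linear assignment
    problem (Min-Cost variant). Returns ``perm`` with perm[k] = index of the
    perturbed internal mode assigned to unperturbed internal mode k.
    """
    O = unperturbed.internal_modes.T @ perturbed.internal_modes
    if O.shape[0] != O.shape[1]:
        raise PerturbScanError("unequal internal-mode counts")
    row, col = linear_sum_assignment(-(O**2))
    perm = np.empty(O.shape[0], dtype=int)
    perm[row] = col
    return perm


def perturbed_subspace(
    S: ModeSubspace, perm: np.ndarray, perturbed: ModeSet
) -> ModeSubspace:
    """Image S^i of subspace S under the mode assignment, in S's order."""
    target = perm[S.mode_indices]
    basis = perturbed.internal_modes[:, target]
    return ModeSubspace(mode_indices=target, basis=basis, label="S_i")


def subspace_similarity(S: ModeSubspace, S_i: ModeSubspace) -> float:
    """Gramian similarity ζ ∈ [0, 1] between two M-mode subspaces.

    Each perturbed mode is projected onto span(S); the Gramian of the
    projections is diagonalized and ζ is the eigenvalue mean. Equals
    (1/M)·Σ_{j,k}(q^i_j·q_k)² (trace identity). 1 ⇔ identical spans,
    0 ⇔ orthogonal.
    """
    if S.M != S_i.M:
        raise PerturbScanError("subspace dimension mismatch")
    A = S.basis.T @ S_i.basis  # (M, M): A[k, j] = q_k · q^i_j
    G = A.T @ A  # Gramian of projections onto span(S)
    lam = np.linalg.eigvalsh(G)
    if lam.min() < -1e-9 or lam.max() > 1.0 + 1e-9:
        raise PerturbScanError("Gramian eigenvalue outside [0, 1]")
    lam = np.clip(lam, 0.0, 1.0)
    return float(lam.sum() / S.M)


def scan_all_residues(
    model: EnmModel,
    modes: ModeSet,
    S: ModeSubspace,
    delta: float = DEFAULT_DELTA,
    neighbor_radius: float = DEFAULT_NEIGHBOR_RADIUS,
) -> ScoreProfile:
    """Perturb every residue at ±δγ, average ζ per residue, Z-score.

    ZscoreS_i = (ζ̄_i − mean)/sd over all residues; also returns the
    neighbor-averaged variant (Cα within ``neighbor_radius``).
    """
    n = len(model.structure)
    zp = np.empty(n)
    zm = np.empty(n)
    for i in range(n):
        for delta_signed, out in ((delta, zp), (-delta, zm)):
            pert_model = perturb_residue(model, i, delta_signed)
            pert_modes = diagonalize(pert_model)
            perm = match_modes(modes, pert_modes)
            S_i = perturbed_subspace(S, perm, pert_modes)
            out[i] = subspace_similarity(S, S_i)
    zmean = 0.5 * (zp + zm)
    sd = zmean.std()
    if sd == 0:
        raise PerturbScanError("degenerate ζ profile (sd = 0)")
    z = (zmean - zmean.mean()) / sd
    z_avg = neighbor_average(z, model.structure, radius=neighbor_radius)
    return ScoreProfile(zeta_plus=zp, zeta_minus=zm, zeta_mean=zmean,
                        zscore=z, zscore_averaged=z_avg)


def neighbor_average(
    values: np.ndarray, structure: CaStructure, radius: float = DEFAULT_NEIGHBOR_RADIUS
) -> np.ndarray:
    """Replace value_i by the mean over residues with Cα within ``radius``
    of residue i (self included)."""
    values = np.asarray(values, dtype=float)
    coords = structure.coords
    diff = coords[:, None, :] - coords[None, :, :]
    within = (diff**2).sum(axis=-1) <= radius**2
    return (within @ values) / within.sum(axis=1)


def select_key_positions(
    profile: ScoreProfile | np.ndarray,
    fraction: float = DEFAULT_KEY_FRACTION,
    use_averaged: bool = False,
) -> KeyPositionSet:
    """The ceil(fraction·N) residues with the lowest ZscoreS.

    Ties at the boundary break by ascending residue index. By default the
    un-averaged ZscoreS ranks residues; ``use_averaged`` switches to the
    7 Å-averaged profile.
    """
    if isinstance(profile, ScoreProfile):
        scores = profile.zscore_averaged if use_averaged else profile.zscore
    else:
        scores = np.asarray(profile, dtype=float)
    n = len(scores)
    if n < 1:
        raise PerturbScanError("empty score profile")
    count = math.ceil(fraction * n - 1e-12)
    order = np.lexsort((np.arange(n), scores))  # ascending score, then index
    idx = np.sort(order[:count])
    return KeyPositionSet(indices=idx, fraction=fraction, count=count)


def write_score_table(
    profile: ScoreProfile, structure: CaStructure, keys: KeyPositionSet, path: str
) -> None:
    """Score TSV: chain, resnum, aa, zeta_plus, zeta_minus, zeta_mean,
    zscore_s, zscore_s_7A, is_key."""
    import pandas as pd

    key_set = set(keys.indices.tolist())
    df = pd.DataFrame({
        "chain": structure.chain_ids,
        "resnum": structure.res_numbers,
        "aa": structure.res_names,
        "zeta_plus": profile.zeta_plus,
        "zeta_minus": profile.zeta_minus,
        "zeta_mean": profile.zeta_mean,
        "zscore_s": profile.zscore,
        "zscore_s_7A": profile.zscore_averaged,
        "is_key": [int(i in key_set) for i in range(len(structure))],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
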