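"""Descriptive analyses of key positions.

Incidence ratios (amino-acid type, SSE class, inter-SSE contact), segment
inertial-axis angle changes between conformers, active-site distances,
heavy-atom contact counts, relative solvent accessibility, and the
correlation report between perturbation scores and structural correlates.
Incidence I > 1 means the feature occurs more often among key positions
than among the remaining residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, spearmanr

from .perturb_scan import KeyPositionSet
from .structio import AnnotationSet, CaStructure, ConformerPair

logger = logging.getLogger(__name__)

SSE_LETTERS = "HBEGITSN"
RSA_EXPOSED_THRESHOLD = 10.0  # %, below = buried
CONTACT_CUTOFF = 5.0  # Å heavy-atom inter-residue contacts

#: maximum accessible surface area (Å²) of residue X in an extended
#: Gly-X-Gly/Ala-X-Ala tripeptide; theoretical values of Tien et al. 2013
#: (PLoS ONE 8:e80635), the standard normalization for percent RSA.
MAX_ACC = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


class CharacterizeError(ValueError):
    pass


@dataclass
class IncidenceReport:
    """Enrichment ratios with their underlying counts.

    ``table`` maps a cell label to (I, n_key, n_rest); cells whose rest
    count is zero are reported with I = None (undefined), never as numbers.
    """

    table: dict[str, tuple[float | None, int, int]]
    kind: str  # "amino_acid" | "sse" | "inter_sse"

    def ratio(self, cell: str) -> float | None:
        return self.table[cell][0]


def _incidence(cat_key: dict[str, int], cat_rest: dict[str, int],
               n_key: int, n_rest: int, cells) -> dict:
    table = {}
    for cell in cells:
        vk, vr = cat_key.get(cell, 0), cat_rest.get(cell, 0)
        if vr == 0 or n_key == 0 or n_rest == 0:
            table[cell] = (None, vk, vr)
        else:
            table[cell] = ((vk / n_key) / (vr / n_rest), vk, vr)
    return table


def incidence_amino_acid(
    keys: KeyPositionSet, structure: CaStructure
) -> IncidenceReport:
    """I_α: frequency of amino-acid type α among key residues over its
    frequency among the rest."""
    if keys.count == 0:
        raise CharacterizeError("empty key-position set")
    key_set = set(keys.indices.tolist())
    ck: dict[str, int] = {}
    cr: dict[str, int] = {}
    for i, aa in enumerate(structure.res_names):
        (ck if i in key_set else cr)[aa] = (ck if i in key_set else cr).get(aa, 0) + 1
    cells = sorted(set(ck) | set(cr))
    n_key = len(key_set)
    n_rest = len(structure) - n_key
    return IncidenceReport(_incidence(ck, cr, n_key, n_rest, cells), "amino_acid")


def incidence_sse(
    keys: KeyPositionSet, annotations: AnnotationSet
) -> IncidenceReport:
    """I_SSE-X: per-DSSP-letter enrichment of key positions."""
    if annotations.sse is None:
        raise CharacterizeError("SSE annotation required")
    sse = np.asarray(annotations.sse)
    key_set = set(keys.indices.tolist())
    ck: dict[str, int] = {}
    cr: dict[str, int] = {}
    for i, letter in enumerate(sse):
        d = ck if i in key_set else cr
        d[letter] = d.get(letter, 0) + 1
    n_key = len(key_set)
    n_rest = len(sse) - n_key
    return IncidenceReport(
        _incidence(ck, cr, n_key, n_rest, list(SSE_LETTERS)), "sse")


def incidence_inter_sse(
    keys: KeyPositionSet, annotations: AnnotationSet, contacts
) -> IncidenceReport:
    """I_inter-SSE(X−Y): among residues on SSE X (X ∈ {E, H}), enrichment of
    key positions that contact a residue on SSE Y.

    Both numerator and denominator count residues on X having at least one
    contact to Y (frequency among keys over frequency among the rest).
    """
    if annotations.sse is None:
        raise CharacterizeError("SSE annotation required")
    sse = np.asarray(annotations.sse)
    key_set = set(keys.indices.tolist())
    return _incidence_inter_sse_impl(sse, key_set, contacts)


def _incidence_inter_sse_impl(sse, key_set, contacts) -> IncidenceReport:
    n = len(sse)
    segment_id = _segment_ids(sse)
    contacted: dict[int, set[str]] = {i: set() for i in range(n)}
    for (i, j), cls in contacts.edges.items():
        if cls == "covalent":
            continue
        if segment_id[i] != segment_id[j]:  # true inter-segment contact
            contacted[i].add(sse[j])
            contacted[j].add(sse[i])
    table = {}
    for X in "EH":
        on_x = [i for i in range(n) if sse[i] == X]
        keys_x = [i for i in on_x if i in key_set]
        rest_x = [i for i in on_x if i not in key_set]
        for Y in SSE_LETTERS:
            cell = f"{X}-{Y}"
            nk = sum(1 for i in keys_x if Y in contacted[i])
            nr = sum(1 for i in rest_x if Y in contacted[i])
            if nr == 0 or not keys_x or not rest_x:
                table[cell] = (None, nk, nr)
            else:
                table[cell] = ((nk / len(keys_x)) / (nr / len(rest_x)), nk, nr)
    return IncidenceReport(table, "inter_sse")


def _segment_ids(sse: np.ndarray) -> np.ndarray:
    """Contiguous runs of an SSE letter share a segment id."""
    ids = np.zeros(len(sse), dtype=int)
    cur = 0
    for i in range(1, len(sse)):
        if sse[i] != sse[i - 1]:
            cur += 1
        ids[i] = cur
    return ids


@dataclass
class SseSegment:
    sse_type: str
    start: int  # 0-based residue index, inclusive
    end: int  # inclusive


def sse_segments(sse: np.ndarray, min_length: int = 3) -> list[SseSegment]:
    """Contiguous SSE runs of at least ``min_length`` residues."""
    segs = []
    start = 0
    for i in range(1, len(sse) + 1):
        if i == len(sse) or sse[i] != sse[start]:
            if i - start >= min_length:
                segs.append(SseSegment(str(sse[start]), start, i - 1))
            start = i
    return segs


def principal_axes(coords: np.ndarray) -> np.ndarray:
    """Three orthonormal principal directions of the Cα gyration tensor,
    descending variance; raises on (near-)collinear segments."""
    centered = coords - coords.mean(axis=0)
    gyr = centered.T @ centered / len(coords)
    w, v = np.linalg.eigh(gyr)
    if w[1] < 1e-10 * max(w[2], 1e-30) or w[2] <= 0:
        raise CharacterizeError("degenerate gyration tensor (collinear segment)")
    return v[:, ::-1].T  # rows = axes, descending variance


def _axis_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle in degrees between two axes, sign-disambiguated to [0°, 90°]."""
    c = abs(float(np.dot(a, b)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def inter_sse_angle_change(
    pair: ConformerPair, seg_x: SseSegment, seg_y: SseSegment
) -> float:
    """Δθ between two SSE segments across the conformational change.

    For each of the three principal inertial axes, the X–Y inter-segment
    angle is computed in the free (θ) and bound (θ′) conformers; Δθ is the
    largest |θ − θ′| over the three axis pairs. Axes are sign-disambiguated
    so every angle lies in [0°, 90°].
    """
    for seg in (seg_x, seg_y):
        if seg.end - seg.start + 1 < 3:
            raise CharacterizeError("segment shorter than 3 residues")
    free_to_bound = {int(f): int(b) for f, b in pair.mapping}
    deltas = []
    ax_f = {}
    ax_b = {}
    for tag, seg in (("x", seg_x), ("y", seg_y)):
        idx_f = np.arange(seg.start, seg.end + 1)
        try:
            idx_b = np.array([free_to_bound[i] for i in idx_f])
        except KeyError as exc:
            raise CharacterizeError(f"segment residue {exc} unmapped in bound") from exc
        ax_f[tag] = principal_axes(pair.free.coords[idx_f])
        ax_b[tag] = principal_axes(pair.bound.coords[idx_b])
    for a in range(3):
        theta = _axis_angle(ax_f["x"][a], ax_f["y"][a])
        theta_p = _axis_angle(ax_b["x"][a], ax_b["y"][a])
        deltas.append(abs(theta - theta_p))
    return float(max(deltas))


def active_site_distance(
    structure: CaStructure, sites: list[list[int]]
) -> np.ndarray:
    """Distance (Å) from each Cα to the nearest active-site Cα centroid."""
    if not sites or any(len(s) == 0 for s in sites):
        raise CharacterizeError("empty active-site list")
    centroids = np.array([structure.coords[list(s)].mean(axis=0) for s in sites])
    d = np.linalg.norm(
        structure.coords[:, None, :] - centroids[None, :, :], axis=-1)
    return d.min(axis=1)


def contact_counts(full_atom_path: str, structure: CaStructure,
                   cutoff: float = CONTACT_CUTOFF) -> np.ndarray:
    """Number of distinct residues j (|i−j| ≥ 2) with any heavy-atom pair
    within ``cutoff`` Å of residue i."""
    from .structio import _load_atom_array, _residue_atom_table
    import biotite.structure as struc

    atoms = _load_atom_array(full_atom_path)
    atoms = atoms[struc.filter_amino_acids(atoms)]
    table, _ = _residue_atom_table(atoms)
    key_to_idx = {k: i for i, k in enumerate(structure.residue_keys())}
    coords = {key_to_idx[k]: np.array(list(v.values()))
              for k, v in table.items() if k in key_to_idx}
    n = len(structure)
    counts = np.zeros(n, dtype=int)
    idxs = sorted(coords)
    for a_pos, i in enumerate(idxs):
        for j in idxs[a_pos + 1:]:
            if abs(i - j) < 2:
                continue
            d = np.linalg.norm(
                coords[i][:, None, :] - coords[j][None, :, :], axis=-1)
            if d.min() <= cutoff:
                counts[i] += 1
                counts[j] += 1
    return counts


def rsa_from_acc(
    acc: np.ndarray, res_names: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Percent RSA from absolute accessibility (DSSP ACC field).

    RSA_i = 100·ACC_i / maxACC(aa_i) with the embedded tripeptide maxima;
    unknown residue types get NaN and a logged flag. Second return value is
    the exposure flag (RSA ≥ 10 %)."""
    rsa = np.full(len(acc), np.nan)
    for i, (a, name) in enumerate(zip(acc, res_names)):
        ref = MAX_ACC.get(str(name))
        if ref is None:
            logger.warning("unknown residue type %r at %d: RSA skipped", name, i)
            continue
        rsa[i] = 100.0 * float(a) / ref
    exposed = rsa >= RSA_EXPOSED_THRESHOLD
    return rsa, exposed


def rsa_from_dssp(dssp_path: str, structure: CaStructure):
    """Per-residue percent RSA for a structure from a DSSP output file."""
    from .structio import read_dssp

    records = {key: (ss, acc) for key, ss, acc in read_dssp(dssp_path)}
    acc = np.full(len(structure), np.nan)
    sse = np.full(len(structure), "N", dtype=object)
    for i, key in enumerate(structure.residue_keys()):
        norm_key = (key[0], key[1], key[2].strip() if key[2] else "")
        if norm_key in records:
            sse[i], acc[i] = records[norm_key]
    rsa, exposed = rsa_from_acc(acc, structure.res_names)
    return rsa, exposed, sse


def residue_correlates(
    zscore_s: np.ndarray,
    zscore_evol: np.ndarray | None = None,
    rsa: np.ndarray | None = None,
    contacts: np.ndarray | None = None,
    rmsd_i: np.ndarray | None = None,
    site_distance: np.ndarray | None = None,
) -> dict[str, dict[str, float]]:
    """Pearson and Spearman coefficients (with p-values) between each score
    and each available structural correlate."""
    scores = {"zscore_s": np.asarray(zscore_s, float)}
    if zscore_evol is not None:
        scores["zscore_evol"] = np.asarray(zscore_evol, float)
    corrs = {
        k: np.asarray(v, float) for k, v in (
            ("rsa", rsa), ("contacts", contacts),
            ("rmsd_i", rmsd_i), ("site_distance", site_distance),
        ) if v is not None
    }
    out: dict[str, dict[str, float]] = {}
    for sname, svec in scores.items():
        for cname, cvec in corrs.items():
            if len(svec) != len(cvec):
                raise CharacterizeError(f"length mismatch {sname} vs {cname}")
            if np.ptp(svec) == 0 or np.ptp(cvec) == 0:
                raise CharacterizeError(f"constant vector in {sname} vs {cname}")
            pr = pearsonr(svec, cvec)
            sr = spearmanr(svec, cvec)
            out[f"{sname}_vs_{cname}"] = {
                "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
                "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
                "n": len(svec),
            }
    return out


def write_incidence_table(report: IncidenceReport, path: str) -> None:
    import pandas as pd

    rows = [
        (cell, (f"{val:.5f}" if val is not None else "NA"), nk, nr)
        for cell, (val, nk, nr) in sorted(
            report.table.items(),
            key=lambda kv: -(kv[1][0] if kv[1][0] is not None else -1.0))
    ]
    pd.DataFrame(rows, columns=["cell", "incidence", "n_key", "n_rest"]).to_csv(
        path, sep="\t", index=False)
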