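"""Structure I/O, conformer pairing/superposition, contact detection and QC.

Structures are reduced to ordered Cα records (:class:`CaStructure`); all
coordinates are in Å and residue indices are 0-based internally (report
writers emit 1-based ranks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

logger = logging.getLogger(__name__)

#: contact classes in precedence order (a pair carries exactly one class)
CONTACT_CLASSES = ("covalent", "disulfide", "hbond_salt", "generic")

_CHARGED_NEG = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_CHARGED_POS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}

HBOND_CUTOFF = 3.5  # Å, any side-chain/backbone N or O pair
SALT_BRIDGE_CUTOFF = 4.0  # Å, opposite-charge side-chain N/O pair
DISULFIDE_CUTOFF = 2.5  # Å, SG–SG


class StructureError(ValueError):
    """Raised for unreadable/invalid structure input."""


@dataclass
class CaStructure:
    """One conformer as an ordered list of Cα records."""

    chain_ids: np.ndarray  # str per residue
    res_numbers: np.ndarray  # int per residue
    icodes: np.ndarray  # str per residue ('' if none)
    res_names: np.ndarray  # 3-letter amino-acid types
    coords: np.ndarray  # (N, 3) Å
    bfactors: np.ndarray  # (N,) Å²
    name: str = ""
    resolution: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.bfactors = np.asarray(self.bfactors, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if np.any(self.bfactors < 0):
            raise StructureError("negative B-factors")
        keys = list(zip(self.chain_ids, self.res_numbers, self.icodes))
        if len(set(keys)) != len(keys):
            raise StructureError("duplicate (chain, resnum, icode) keys")

    def __len__(self) -> int:
        return len(self.res_numbers)

    @property
    def n_residues(self) -> int:
        return len(self.res_numbers)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        return list(zip(self.chain_ids, self.res_numbers, self.icodes))


@dataclass
class ConformerPair:
    """Ligand-free / ligand-bound conformers of the same protein, superposed.

    ``bound`` coordinates are rigidly transformed onto ``free`` by
    least-squares (Kabsch) superposition over the mapped Cα.
    """

    free: CaStructure
    bound: CaStructure
    mapping: np.ndarray  # (M, 2) index pairs (free_idx, bound_idx)
    rmsd: float  # global Cα RMSD after superposition, Å
    rmsd_per_residue: np.ndarray  # (M,) Å


@dataclass
class ContactGraph:
    """Typed residue–residue contacts feeding the spring-constant rules."""

    edges: dict[tuple[int, int], str]  # (i<j) -> contact class
    r_c: float
    distances: dict[tuple[int, int], float] = field(default_factory=dict)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for (a, b) in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out


@dataclass
class AnnotationSet:
    """Per-residue annotations consumed by the characterization stage."""

    sse: np.ndarray | None = None  # DSSP 8-letter codes, 'N' = unclassified
    rsa: np.ndarray | None = None  # relative accessibility, %
    active_sites: list[list[int]] | None = None  # residue-index sets
    contacts_per_residue: np.ndarray | None = None


# ---------------------------------------------------------------------------
# reading


def _load_atom_array(path: str) -> struc.AtomArray:
    """Read the first model, resolving altlocs to the highest-occupancy
    variant (ties keep the first-listed, i.e. 'A')."""
    try:
        f = pdb.PDBFile.read(path)
    except Exception as exc:  # pragma: no cover - biotite raises varied types
        raise StructureError(f"unreadable PDB file {path!r}: {exc}") from exc
    try:
        atoms = f.get_structure(
            model=1, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
        )
    except Exception as exc:
        raise StructureError(f"invalid PDB content in {path!r}: {exc}") from exc
    if atoms.array_length() == 0:
        raise StructureError(f"no ATOM records in {path!r}")
    return atoms


def read_ca_structure(
    path: str, chain: str | None = None, name: str = "", resolution: float | None = None
) -> CaStructure:
    """Read one chain of a PDB file as an ordered Cα trace.

    Residues lacking a Cα atom are reported via logging and excluded.
    Altloc records keep the highest-occupancy variant (ties -> 'A').
    """
    atoms = _load_atom_array(path)
    if chain is not None:
        if chain not in set(atoms.chain_id):
            raise StructureError(f"chain {chain!r} not in {path!r}")
        atoms = atoms[atoms.chain_id == chain]
    atoms = atoms[struc.filter_amino_acids(atoms)]
    ca = atoms[atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise StructureError(f"no Cα atoms for chain {chain!r} in {path!r}")

    # report residues missing a Cα
    res_keys_all = {
        (c, int(r), ic)
        for c, r, ic in zip(atoms.chain_id, atoms.res_id, atoms.ins_code)
    }
    res_keys_ca = {
        (c, int(r), ic)
        for c, r, ic in zip(ca.chain_id, ca.res_id, ca.ins_code)
    }
    missing = res_keys_all - res_keys_ca
    if missing:
        logger.warning("%d residue(s) lack a Cα and were excluded: %s",
                       len(missing), sorted(missing)[:5])

    return CaStructure(
        chain_ids=np.asarray(ca.chain_id, dtype=object),
        res_numbers=np.asarray(ca.res_id, dtype=int),
        icodes=np.asarray(ca.ins_code, dtype=object),
        res_names=np.asarray(ca.res_name, dtype=object),
        coords=np.asarray(ca.coord, dtype=float),
        bfactors=np.asarray(ca.b_factor, dtype=float),
        name=name or path,
        resolution=resolution,
    )


# ---------------------------------------------------------------------------
# superposition


def kabsch_transform(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid transform (R, t) minimizing ||R·mobile + t − target||²."""
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    return R, t


def pair_and_superpose(free: CaStructure, bound: CaStructure) -> ConformerPair:
    """Map residues by (chain, resnum, icode) and superpose bound onto free.

    Raises on <3 mapped residues, collinear mapped Cα, or amino-acid type
    mismatch at a mapped position (conformer pairs are the same protein).
    """
    free_index = {k: i for i, k in enumerate(free.residue_keys())}
    pairs = []
    for j, key in enumerate(bound.residue_keys()):
        i = free_index.get(key)
        if i is not None:
            if free.res_names[i] != bound.res_names[j]:
                raise StructureError(
                    f"amino-acid mismatch at {key}: "
                    f"{free.res_names[i]} vs {bound.res_names[j]}"
                )
            pairs.append((i, j))
    if len(pairs) < 3:
        raise StructureError(f"only {len(pairs)} mapped residues (need ≥ 3)")
    mapping = np.asarray(pairs, dtype=int)

    x = free.coords[mapping[:, 0]]
    y = bound.coords[mapping[:, 1]]
    # non-collinearity: rank of centered coordinates must exceed 1
    if np.linalg.matrix_rank(x - x.mean(axis=0), tol=1e-8) < 2:
        raise StructureError("mapped Cα are collinear; superposition ill-posed")

    R, t = kabsch_transform(y, x)
    bound_coords = bound.coords @ R.T + t
    y_fit = bound_coords[mapping[:, 1]]
    d = np.linalg.norm(y_fit - x, axis=1)
    rmsd = float(np.sqrt(np.mean(d**2)))

    bound_sup = CaStructure(
        chain_ids=bound.chain_ids.copy(),
        res_numbers=bound.res_numbers.copy(),
        icodes=bound.icodes.copy(),
        res_names=bound.res_names.copy(),
        coords=bound_coords,
        bfactors=bound.bfactors.copy(),
        name=bound.name,
        resolution=bound.resolution,
    )
    return ConformerPair(
        free=free, bound=bound_sup, mapping=mapping, rmsd=rmsd, rmsd_per_residue=d
    )


# ---------------------------------------------------------------------------
# contact detection


def _residue_atom_table(atoms: struc.AtomArray):
    """Group heavy atoms by (chain, resnum, icode)."""
    heavy = atoms[atoms.element != "H"]
    table: dict[tuple, dict[str, np.ndarray]] = {}
    names: dict[tuple, str] = {}
    for idx in range(heavy.array_length()):
        key = (heavy.chain_id[idx], int(heavy.res_id[idx]), heavy.ins_code[idx])
        table.setdefault(key, {})[heavy.atom_name[idx]] = heavy.coord[idx]
        names[key] = heavy.res_name[idx]
    return table, names


def _is_no(atom_name: str) -> bool:
    return atom_name.startswith(("N", "O"))


def detect_contacts(
    structure: CaStructure,
    full_atom_path: str | None = None,
    r_c: float = 10.0,
) -> ContactGraph:
    """Classify residue pairs into typed contacts.

    Precedence: covalent (|i−j| = 1) > disulfide (CYS SG–SG ≤ 2.5 Å) >
    hbond-or-saltbridge (geometric N/O rules) > generic (Cα ≤ r_c).
    The disulfide class is not distance-gated by r_c; hbond and generic are.
    Without full-atom records only {covalent, generic} are detected.
    """
    n = len(structure)
    coords = structure.coords
    edges: dict[tuple[int, int], str] = {}
    dists: dict[tuple[int, int], float] = {}

    hb_pairs: set[tuple[int, int]] = set()
    ss_pairs: set[tuple[int, int]] = set()
    if full_atom_path is not None:
        atoms = _load_atom_array(full_atom_path)
        atoms = atoms[struc.filter_amino_acids(atoms)]
        table, fa_names = _residue_atom_table(atoms)
        key_to_idx = {k: i for i, k in enumerate(structure.residue_keys())}
        for key in table:
            i = key_to_idx.get(key)
            if i is not None and fa_names[key] != structure.res_names[i]:
                raise StructureError(f"residue mismatch at {key} between Cα and full-atom records")
        keys = [k for k in table if k in key_to_idx]
        for a_pos, ka in enumerate(keys):
            ia = key_to_idx[ka]
            for kb in keys[a_pos + 1:]:
                ib = key_to_idx[kb]
                pair = (min(ia, ib), max(ia, ib))
                aa, ab = table[ka], table[kb]
                na, nb = fa_names[ka], fa_names[kb]
                # disulfide
                if na == "CYS" and nb == "CYS" and "SG" in aa and "SG" in ab:
                    if np.linalg.norm(aa["SG"] - ab["SG"]) <= DISULFIDE_CUTOFF:
                        ss_pairs.add(pair)
                        continue
                if _polar_contact(aa, ab, na, nb):
                    hb_pairs.add(pair)
    else:
        logger.warning(
            "no full-atom records: contacts degrade to {covalent, generic} only"
        )

    diff = coords[:, None, :] - coords[None, :, :]
    dmat = np.sqrt((diff**2).sum(axis=-1))
    for i in range(n):
        for j in range(i + 1, n):
            pair = (i, j)
            same_chain = structure.chain_ids[i] == structure.chain_ids[j]
            if same_chain and j == i + 1:
                cls = "covalent"
            elif pair in ss_pairs:
                cls = "disulfide"
            elif pair in hb_pairs and dmat[i, j] <= r_c:
                cls = "hbond_salt"
            elif dmat[i, j] <= r_c:
                cls = "generic"
            else:
                continue
            edges[pair] = cls
            dists[pair] = float(dmat[i, j])
    return ContactGraph(edges=edges, r_c=r_c, distances=dists)


def _polar_contact(aa: dict, ab: dict, na: str, nb: str) -> bool:
    """Hydrogen bond or salt bridge by geometric rule (CSU surrogate)."""
    # salt bridge: opposite-charge side-chain N/O pair at ≤ 4.0 Å
    for neg, pos in ((na, nb), (nb, na)):
        if neg in _CHARGED_NEG and pos in _CHARGED_POS:
            neg_atoms = aa if neg == na else ab
            pos_atoms = ab if neg == na else aa
            for an in _CHARGED_NEG[neg]:
                for ap in _CHARGED_POS[pos]:
                    if an in neg_atoms and ap in pos_atoms:
                        if np.linalg.norm(neg_atoms[an] - pos_atoms[ap]) <= SALT_BRIDGE_CUTOFF:
                            return True
    # hydrogen bond: any N/O pair at ≤ 3.5 Å
    a_no = [v for k, v in aa.items() if _is_no(k)]
    b_no = [v for k, v in ab.items() if _is_no(k)]
    for pa in a_no:
        for pb in b_no:
            if np.linalg.norm(pa - pb) <= HBOND_CUTOFF:
                return True
    return False


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    """Pass/fail per dataset-curation criterion (report only, never raises)."""

    resolution_ok: bool
    complete_ok: bool
    bfactor_spearman_ok: bool
    coverage_ok: bool
    homologs_ok: bool

    @property
    def all_pass(self) -> bool:
        return all(
            (self.resolution_ok, self.complete_ok, self.bfactor_spearman_ok,
             self.coverage_ok, self.homologs_ok)
        )

    def as_dict(self) -> dict[str, bool]:
        return {
            "resolution_lt_4A": self.resolution_ok,
            "no_missing_residues": self.complete_ok,
            "bfactor_spearman_gt_0.4": self.bfactor_spearman_ok,
            "msa_coverage_ge_0.8": self.coverage_ok,
            "homologs_gt_100": self.homologs_ok,
        }


def qc_pair(
    pair: ConformerPair,
    bfactor_spearman: float,
    msa_coverage: float,
    n_homologs: int,
    complete: bool = True,
) -> QCReport:
    """Apply the dataset curation filters: resolution < 4 Å, no missing
    residues, optimal B-factor Spearman > 0.4, MSA coverage ≥ 80 %, and
    more than 100 homologs."""
    resolutions = [r for r in (pair.free.resolution, pair.bound.resolution)
                   if r is not None]
    res_ok = all(r < 4.0 for r in resolutions) if resolutions else True
    return QCReport(
        resolution_ok=res_ok,
        complete_ok=bool(complete),
        bfactor_spearman_ok=bfactor_spearman > 0.4,
        coverage_ok=msa_coverage >= 0.8,
        homologs_ok=n_homologs > 100,
    )


# ---------------------------------------------------------------------------
# DSSP


def read_dssp(path: str):
    """Parse a DSSP output file into per-residue (key, sse_letter, acc).

    Returns a list of ((chain, resnum, icode), sse, acc) in file order.
    Unclassified residues get 'N'.
    """
    from Bio.PDB.DSSP import make_dssp_dict

    dssp_dict, keys = make_dssp_dict(path)
    out = []
    for key in keys:
        chain, (het, resnum, icode) = key
        aa, ss, acc = dssp_dict[key][0], dssp_dict[key][1], dssp_dict[key][2]
        ss = ss if ss in "HBEGITS" else "N"
        out.append(((chain, int(resnum), icode.strip()), ss, float(acc)))
    return out


def write_pair_report(pair: ConformerPair, path: str) -> None:
    """Pair report TSV: chain, resnum (1-based PDB numbering), aa, rmsd_i,
    B-factors of both conformers."""
    import pandas as pd

    fi = pair.mapping[:, 0]
    bi = pair.mapping[:, 1]
    df = pd.DataFrame({
        "chain": pair.free.chain_ids[fi],
        "resnum": pair.free.res_numbers[fi],
        "aa": pair.free.res_names[fi],
        "rmsd_i": pair.rmsd_per_residue,
        "bfactor_free": pair.free.bfactors[fi],
        "bfactor_bound": pair.bound.bfactors[bi],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
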