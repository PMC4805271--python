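"""Seeded synthetic fixtures with known ground truth.

Generates Cα bead proteins with realistic contact topology (compact
solenoid domains bridged by a narrow hinge), bound conformers displaced
along chosen internal modes, ENM-consistent noisy B-factors, and MSAs whose
column conservation is statistically coupled to a supplied per-residue
score. Every output is a deterministic function of (spec, seed); the
random streams for geometry, B-factor noise and MSA sampling are
independent so changing one does not shift the others.

Fixtures are written as standard PDB / aligned FASTA so they flow through
the public readers rather than private constructors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conservation import AA_ALPHABET, AlignmentSet
from .enm_core import ModeSet, theoretical_bfactors
from .structio import CaStructure

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
AA1 = {v: k for k, v in AA3.items()}

CA_SPACING = 3.8  # Å, consecutive Cα
BFACTOR_FLOOR = 0.01


class SynthError(ValueError):
    pass


@dataclass
class FixtureSpec:
    seed: int = 0
    topology: str = "two-domain-hinge"  # | "helix-pair" | "random-globule"
    n_residues: int = 60
    planted_modes: list[tuple[int, float]] = field(default_factory=list)
    bfactor_noise_sd: float = 0.0
    msa_rows: int = 150
    msa_coupling: float = 1.0
    msa_noise_sd: float = 0.5


@dataclass
class GroundTruth:
    hinge_indices: np.ndarray  # residues forming the inter-domain bridge
    region_indices: np.ndarray  # hinge + its 8 Å contact shell
    domain_a: np.ndarray
    domain_b: np.ndarray


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, stream]))


MIN_BEAD_SEPARATION = 3.4  # Å, non-bonded Cα clash distance


def _alpha_helix(n: int) -> np.ndarray:
    """Ideal α-helix Cα trace: radius 2.3 Å, rise 1.5 Å, 100° per residue."""
    k = np.arange(n)
    t = np.radians(100.0) * k
    return np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * k])


def _compact_walk(
    n: int, rng: np.random.Generator, start: np.ndarray, center: np.ndarray,
    radius: float, obstacles: np.ndarray | None = None,
) -> np.ndarray:
    """Self-avoiding chain of n beads (3.8 Å steps, ≥ 3.4 Å non-bonded
    separation) confined to a sphere — a compact globular domain with
    realistic contact density. Avoids ``obstacles`` (coordinates of an
    already-placed chain); backtracks when trapped."""
    beads = [np.asarray(start, dtype=float)]
    tries = 0
    restarts = 0
    while len(beads) < n:
        pos = beads[-1]
        placed = False
        for _ in range(300):
            d = rng.normal(size=3)
            # bias steps toward the sphere interior to stay compact
            d = d / np.linalg.norm(d) + 0.8 * (center - pos) / radius
            d /= np.linalg.norm(d)
            cand = pos + CA_SPACING * d
            if np.linalg.norm(cand - center) > radius:
                continue
            if len(beads) > 1:
                dist = np.linalg.norm(np.asarray(beads[:-1]) - cand, axis=1)
                if dist.min() < MIN_BEAD_SEPARATION:
                    continue
            if obstacles is not None:
                if np.linalg.norm(obstacles - cand, axis=1).min() < MIN_BEAD_SEPARATION:
                    continue
            beads.append(cand)
            placed = True
            break
        if not placed:
            tries += 1
            if tries > 50 or len(beads) <= 1:
                if restarts >= 20:
                    raise SynthError(
                        f"could not grow compact domain of {n} beads in "
                        f"radius {radius:.1f} Å")
                restarts += 1
                tries = 0
                beads = [np.asarray(start, dtype=float)]  # restart chain
            else:
                beads.pop()  # backtrack one step and retry
    return np.asarray(beads)


def _domain_radius(n: int) -> float:
    """Confinement radius giving roughly globular-protein packing density."""
    return max(6.5, 2.6 * n ** (1 / 3) + 1.5)


def _grow_two_domain(rng, n_a: int, n_b: int, n_hinge: int) -> np.ndarray:
    """Two compact walk domains joined by a kinked 3-bead bridge."""
    # domain A grown downward from its north pole; reversed so the chain
    # exits at the surface, where the hinge attaches
    r_a, r_b = _domain_radius(n_a), _domain_radius(n_b)
    dom_a = _compact_walk(
        n_a, rng, start=np.array([0.0, 0.0, r_a - 0.5]),
        center=np.zeros(3), radius=r_a)[::-1]
    out_dir = np.array([0.0, 0.0, 1.0])
    # kinked bridge: laterally staggered beads, mutually non-collinear
    offsets = np.array([[1.5, 0.0, 3.0], [0.0, 1.5, 6.0], [-1.0, -0.5, 9.0]])
    hinge = dom_a[-1] + offsets[:n_hinge]
    entry = hinge[-1] + np.array([0.5, -0.5, 3.0])
    # overlap the confinement spheres slightly so the domains also share a
    # direct contact patch near the bridge, as hinged two-domain proteins do
    center_b = entry + out_dir * (r_b - 4.5)
    dom_b = _compact_walk(n_b, rng, start=entry, center=center_b,
                          radius=r_b, obstacles=np.vstack([dom_a, hinge]))
    return np.vstack([dom_a, hinge, dom_b])


def _is_rigid(coords: np.ndarray, r_c: float) -> bool:
    """True when the classed-spring network has exactly 6 zero modes."""
    import scipy.linalg

    from .structio import CaStructure as _CaS
    from . import enm_core as _enm

    n = len(coords)
    tmp = _CaS(
        chain_ids=np.array(["A"] * n, dtype=object),
        res_numbers=np.arange(1, n + 1),
        icodes=np.array([""] * n, dtype=object),
        res_names=np.array(["ALA"] * n, dtype=object),
        coords=coords, bfactors=np.ones(n))
    from .structio import detect_contacts as _dc
    contacts = _dc(tmp, None, r_c=r_c)
    springs = _enm.assign_force_constants(contacts)
    H = _enm.build_hessian(tmp, springs).hessian
    w = scipy.linalg.eigh(H, eigvals_only=True)
    tol = _enm.NULL_MODE_RTOL * max(w[-1], 1.0)
    return int(np.sum(w < tol)) == 6


def make_structure(spec: FixtureSpec) -> tuple[CaStructure, GroundTruth]:
    """Deterministic two-domain bead structure with a narrow hinge bridge.

    Two compact self-avoiding-walk domains are joined by a short kinked
    bridge and share a small contact patch; a seeded jitter breaks
    symmetry. The network is verified rigid (exactly 6 zero modes at
    r_c = 10 Å) before being returned.
    """
    if spec.n_residues < 10:
        raise SynthError("need N ≥ 10 residues")
    rng = _rng(spec.seed, 0)
    n = spec.n_residues
    # the bridge must be short (every bead inside generic-spring range of
    # both domain surfaces) and non-collinear: three non-collinear anchors
    # between the domains block the free relative torsion a straight
    # tether would leave about the inter-domain axis
    n_hinge = 3
    n_a = (n - n_hinge) // 2
    n_b = n - n_hinge - n_a

    if spec.topology == "random-globule":
        r = _domain_radius(n)
        coords = _compact_walk(n, rng, start=np.array([0.0, 0.0, r]),
                               center=np.zeros(3), radius=r)
        hinge_idx = np.array([], dtype=int)
    elif spec.topology == "helix-pair":
        h1 = _alpha_helix(n_a)
        link = h1[-1] + np.array([4.5, 0, 0]) * np.arange(1, n_hinge + 1)[:, None]
        # second helix tilted ~50° from the first: the inter-axis angle
        # sits mid-range, away from the 0°/90° folding ambiguity
        phi = np.radians(50.0)
        tilt = np.array([[1.0, 0.0, 0.0],
                         [0.0, np.cos(phi), -np.sin(phi)],
                         [0.0, np.sin(phi), np.cos(phi)]])
        h2 = _alpha_helix(n_b) @ tilt.T
        h2 = h2 - h2[0] + link[-1] + np.array([4.5, 0.0, 0.0])
        coords = np.vstack([h1, link, h2])
        hinge_idx = np.arange(n_a, n_a + n_hinge)
    elif spec.topology == "two-domain-hinge":
        # rejection sampling: a rare walk can still leave the bridge
        # under-braced (a residual inter-domain mechanism); regenerate from
        # the same stream until the network is rigid, so the output stays a
        # deterministic function of the seed
        for _attempt in range(30):
            coords = _grow_two_domain(rng, n_a, n_b, n_hinge)
            coords = coords + rng.normal(0.0, 0.15, size=coords.shape)
            if _is_rigid(coords, r_c=10.0):
                break
        else:
            raise SynthError("could not generate a rigid two-domain network")
        hinge_idx = np.arange(n_a, n_a + n_hinge)
    else:
        raise SynthError(f"unknown topology {spec.topology!r}")
    if spec.topology != "two-domain-hinge":
        coords = coords + rng.normal(0.0, 0.15, size=coords.shape)

    letters = rng.choice(list(AA_ALPHABET), size=n)
    res_names = np.array([AA3[l] for l in letters], dtype=object)
    structure = CaStructure(
        chain_ids=np.array(["A"] * n, dtype=object),
        res_numbers=np.arange(1, n + 1),
        icodes=np.array([""] * n, dtype=object),
        res_names=res_names,
        coords=coords,
        bfactors=np.ones(n),
        name=f"synthetic-{spec.topology}-{spec.seed}",
    )

    # ground-truth "hinge/contact region": the bridge residues plus every
    # residue carrying an inter-domain contact (these springs store the
    # strain of the hinge-bending modes)
    idx_a = np.arange(0, n_a)
    idx_b = np.arange(n_a + n_hinge, n)
    if len(hinge_idx):
        d_ab = np.linalg.norm(
            coords[idx_a][:, None, :] - coords[idx_b][None, :, :], axis=-1)
        touching_a = idx_a[(d_ab <= 10.0).any(axis=1)]
        touching_b = idx_b[(d_ab <= 10.0).any(axis=0)]
        region = np.unique(np.concatenate([hinge_idx, touching_a, touching_b]))
    else:
        region = np.array([], dtype=int)
    truth = GroundTruth(
        hinge_indices=hinge_idx,
        region_indices=region,
        domain_a=np.arange(0, n_a),
        domain_b=np.arange(n_a + n_hinge, n),
    )
    return structure, truth


def make_bound(
    free: CaStructure,
    modes: ModeSet,
    planted: list[tuple[int, float]],
    seed: int = 0,
    rigid_transform: bool = True,
    check_topology_at: float | None = None,
) -> CaStructure:
    """Bound conformer: free + Σ amplitude·q_k, then an arbitrary rigid
    transform (to exercise superposition).

    ``planted`` lists (internal-mode position, amplitude in Å·residue^½);
    positions index the internal modes (0 = lowest-frequency). With
    ``check_topology_at`` set to a cutoff radius, an amplitude that
    changes the contact set at that radius raises."""
    n_internal = modes.internal_modes.shape[1]
    disp = np.zeros(3 * len(free))
    for pos, amp in planted:
        if not 0 <= pos < n_internal:
            raise SynthError(f"mode position {pos} outside internal range")
        disp += amp * modes.internal_modes[:, pos]
    coords = free.coords + disp.reshape(-1, 3)
    if check_topology_at is not None:
        r_c = check_topology_at
        def edge_set(c):
            d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
            iu = np.triu_indices(len(c), 1)
            return set(zip(*[a[d[iu] <= r_c] for a in iu]))
        if edge_set(free.coords) != edge_set(coords):
            raise SynthError(
                "planted amplitude changes the contact topology "
                f"at r_c = {r_c} Å")
    if rigid_transform:
        rng = _rng(seed, 1)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        coords = coords @ Q.T + rng.uniform(-20, 20, size=3)
    return CaStructure(
        chain_ids=free.chain_ids.copy(),
        res_numbers=free.res_numbers.copy(),
        icodes=free.icodes.copy(),
        res_names=free.res_names.copy(),
        coords=coords,
        bfactors=free.bfactors.copy(),
        name=free.name + "-bound",
    )


def make_bfactors(
    modes: ModeSet, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """Experimental-style B-factors: theoretical ENM profile plus seeded
    Gaussian noise, floored at a small positive value.

    The profile is rescaled to a crystallographic mean of 30 Å² (the ENM
    scale is arbitrary and only ranks are consumed downstream; PDB files
    cannot hold arbitrarily large B values)."""
    profile = theoretical_bfactors(modes).values
    profile = profile * (30.0 / profile.mean())
    if noise_sd > 0:
        rng = _rng(seed, 2)
        profile = profile + rng.normal(0.0, noise_sd, size=profile.shape)
    return np.maximum(profile, BFACTOR_FLOOR)


def make_coupled_msa(
    reference: np.ndarray | str,
    score: np.ndarray,
    coupling: float = 1.0,
    n_rows: int = 150,
    seed: int = 0,
    noise_sd: float = 0.5,
    base_sub_prob: float = 0.3,
) -> AlignmentSet:
    """MSA whose column-wise conservation is coupled to a score profile.

    Per column i the substitution probability is
    logistic(logit(base) + coupling·score_i + η_i), η_i ~ N(0, noise_sd):
    columns with low score (e.g. low ZscoreS, i.e. dynamically critical)
    mutate rarely and come out conserved, so downstream Zscore_evol
    correlates negatively with the supplied score. Row 0 is the unaltered
    reference.
    """
    if not 0 <= coupling:
        raise SynthError("coupling must be ≥ 0")
    ref = np.array(list(reference)) if isinstance(reference, str) else np.asarray(reference)
    score = np.asarray(score, dtype=float)
    if len(ref) != len(score):
        raise SynthError("reference and score lengths differ")
    rng = _rng(seed, 3)
    logit0 = np.log(base_sub_prob / (1 - base_sub_prob))
    eta = rng.normal(0.0, noise_sd, size=len(score))
    p_sub = 1.0 / (1.0 + np.exp(-(logit0 + coupling * score + eta)))

    alphabet = np.array(list(AA_ALPHABET))
    rows = [ref.copy()]
    for _ in range(n_rows):
        row = ref.copy()
        mask = rng.random(len(ref)) < p_sub
        if mask.any():
            row[mask] = alphabet[rng.integers(0, 20, size=mask.sum())]
        rows.append(row)
    ids = ["reference"] + [f"homolog_{k:04d}" for k in range(n_rows)]
    return AlignmentSet(ids=ids, rows=np.array(rows), reference=0)


# ---------------------------------------------------------------------------
# writers (fixtures travel through the public readers)

_SIDECHAIN_ATOMS = {
    "CYS": ("SG", "S"),
    "ASP": ("OD1", "O"),
    "GLU": ("OE1", "O"),
    "LYS": ("NZ", "N"),
    "ARG": ("NH1", "N"),
    "HIS": ("NE2", "N"),
    "SER": ("OG", "O"),
}


def write_structure_pdb(
    structure: CaStructure, path: str, full_atom: bool = False
) -> None:
    """Write the fixture as a PDB file; with ``full_atom`` a pseudo
    side-chain atom per bead (CB plus a polar tip for charged/polar types)
    is added so the contact-class code paths run."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    records = []
    center = structure.coords.mean(axis=0)
    for i in range(len(structure)):
        ca = structure.coords[i]
        records.append((i, "CA", "C", ca))
        if full_atom:
            out_dir = ca - center
            nrm = np.linalg.norm(out_dir)
            out_dir = out_dir / nrm if nrm > 1e-6 else np.array([0.0, 0.0, 1.0])
            name3 = str(structure.res_names[i])
            if name3 != "GLY":
                records.append((i, "CB", "C", ca + 1.5 * out_dir))
            tip = _SIDECHAIN_ATOMS.get(name3)
            if tip is not None:
                records.append((i, tip[0], tip[1], ca + 2.8 * out_dir))
    atoms = struc.AtomArray(len(records))
    atoms.add_annotation("b_factor", float)
    atoms.add_annotation("occupancy", float)
    for pos, (i, aname, elem, coord) in enumerate(records):
        atoms.chain_id[pos] = str(structure.chain_ids[i])
        atoms.res_id[pos] = int(structure.res_numbers[i])
        atoms.ins_code[pos] = str(structure.icodes[i])
        atoms.res_name[pos] = str(structure.res_names[i])
        atoms.atom_name[pos] = aname
        atoms.element[pos] = elem
        atoms.hetero[pos] = False
        atoms.coord[pos] = coord
        atoms.b_factor[pos] = float(structure.bfactors[i])
        atoms.occupancy[pos] = 1.0
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(path)


def write_alignment_fasta(aln: AlignmentSet, path: str) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{''.join(row)}\n")
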