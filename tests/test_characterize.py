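"""Incidence tables, SSE geometry, active-site distances, correlates."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from confkeys import characterize as chz
from confkeys import perturb_scan, structio, synthdata
from confkeys.characterize import CharacterizeError, SseSegment

from conftest import copy_with_coords, make_ca


def _keys(indices, n):
    idx = np.asarray(sorted(indices), dtype=int)
    return perturb_scan.KeyPositionSet(indices=idx, fraction=len(idx) / n,
                                       count=len(idx))


class TestIncidenceAminoAcid:
    def test_null_uniform_sampling_expectation(self):
        """Randomly assigned key labels give incidence ≈ 1 in expectation."""
        rng = np.random.default_rng(5)
        names = rng.choice(["ALA", "VAL", "LEU", "GLY"], size=200)
        s = make_ca(rng.uniform(0, 60, (200, 3)), res_names=names)
        acc: dict[str, list] = {}
        for _ in range(400):
            keys = _keys(rng.choice(200, size=40, replace=False), 200)
            rep = chz.incidence_amino_acid(keys, s)
            for cell, (val, *_counts) in rep.table.items():
                if val is not None:
                    acc.setdefault(cell, []).append(val)
        for cell, vals in acc.items():
            assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_enriched_type_exceeds_one(self):
        names = ["CYS", "CYS"] + ["ALA"] * 38
        s = make_ca(np.random.default_rng(7).uniform(0, 30, (40, 3)),
                    res_names=names)
        rep = chz.incidence_amino_acid(_keys([0, 1], 40), s)
        assert rep.ratio("CYS") is None or rep.ratio("CYS") > 1  # CYS absent in rest
        assert rep.table["CYS"][1] == 2 and rep.table["CYS"][2] == 0

    def test_hand_counts(self):
        names = ["ALA"] * 6 + ["VAL"] * 4
        s = make_ca(np.random.default_rng(9).uniform(0, 30, (10, 3)),
                    res_names=names)
        rep = chz.incidence_amino_acid(_keys([0, 6], 10), s)
        # keys: 1 ALA + 1 VAL of 2; rest: 5 ALA + 3 VAL of 8
        assert rep.ratio("ALA") == pytest.approx((1 / 2) / (5 / 8))
        assert rep.ratio("VAL") == pytest.approx((1 / 2) / (3 / 8))


class TestIncidenceSse:
    def test_all_keys_on_strands(self):
        sse = np.array(list("EEEEHHHHTTTT"))
        ann = structio.AnnotationSet(sse=sse)
        rep = chz.incidence_sse(_keys([0, 1], 12), ann)
        assert rep.ratio("E") > 1
        assert rep.table["H"][1] == 0

    def test_hand_counts(self):
        sse = np.array(list("EEHHHT"))
        ann = structio.AnnotationSet(sse=sse)
        rep = chz.incidence_sse(_keys([0, 2], 6), ann)
        assert rep.ratio("E") == pytest.approx((1 / 2) / (1 / 4))
        assert rep.ratio("H") == pytest.approx((1 / 2) / (2 / 4))


class TestIncidenceInterSse:
    def _graph(self, edges, n):
        return structio.ContactGraph(
            edges={(min(i, j), max(i, j)): c for i, j, c in edges}, r_c=10.0)

    def test_no_inter_sse_contacts_all_undefined(self):
        sse = np.array(list("EEEHHH"))
        ann = structio.AnnotationSet(sse=sse)
        g = self._graph([(0, 1, "covalent")], 6)
        rep = chz.incidence_inter_sse(_keys([0], 6), ann, g)
        assert all(v is None for v, *_ in rep.table.values())

    def test_bridging_key_residue_enriched(self):
        sse = np.array(list("EEEHHHEEE"))
        ann = structio.AnnotationSet(sse=sse)
        # strand residues 1 (key) and 7 (not key) both contact the helix
        g = self._graph([(1, 4, "generic"), (7, 4, "generic")], 9)
        rep = chz.incidence_inter_sse(_keys([1], 9), ann, g)
        # among E residues: key fraction with H contact 1/1, rest 1/5
        assert rep.ratio("E-H") == pytest.approx((1 / 1) / (1 / 5))


@pytest.fixture(scope="module")
def helix_pair():
    spec = synthdata.FixtureSpec(seed=2, topology="helix-pair", n_residues=33)
    free, _ = synthdata.make_structure(spec)
    n_a = (33 - 3) // 2
    segs = (SseSegment("H", 0, n_a - 1), SseSegment("H", n_a + 3, 32))
    return free, segs


class TestAngleChange:
    def _pair(self, free, bound_coords):
        n = len(free)
        bound = copy_with_coords(free, bound_coords)
        return structio.ConformerPair(
            free=free, bound=bound,
            mapping=np.column_stack([np.arange(n)] * 2),
            rmsd=0.0, rmsd_per_residue=np.zeros(n))

    def test_identical_conformers_zero(self, helix_pair):
        free, (sx, sy) = helix_pair
        pair = self._pair(free, free.coords.copy())
        assert chz.inter_sse_angle_change(pair, sx, sy) == pytest.approx(0.0, abs=1e-9)

    def test_twenty_degree_rotation_recovered(self, helix_pair):
        """Helix Y rotated rigidly by 20° about an axis normal to its long
        axis: Δθ = 20° ± 0.5°."""
        free, (sx, sy) = helix_pair
        idx = np.arange(sy.start, sy.end + 1)
        ax_y = chz.principal_axes(free.coords[idx])[0]
        ax_x = chz.principal_axes(
            free.coords[np.arange(sx.start, sx.end + 1)])[0]
        # rotate in the plane of the two helix axes: the inter-axis angle
        # then changes by exactly the applied rotation
        normal = np.cross(ax_x, ax_y)
        normal /= np.linalg.norm(normal)
        R = Rotation.from_rotvec(np.radians(20.0) * normal).as_matrix()
        coords = free.coords.copy()
        cen = coords[idx].mean(axis=0)
        coords[idx] = (coords[idx] - cen) @ R.T + cen
        pair = self._pair(free, coords)
        dtheta = chz.inter_sse_angle_change(pair, sx, sy)
        assert dtheta == pytest.approx(20.0, abs=0.5)

    def test_invariant_to_global_rigid_transform(self, helix_pair):
        free, (sx, sy) = helix_pair
        rng = np.random.default_rng(3)
        idx = np.arange(sy.start, sy.end + 1)
        ax_y = chz.principal_axes(free.coords[idx])[0]
        ax_x = chz.principal_axes(
            free.coords[np.arange(sx.start, sx.end + 1)])[0]
        # rotate in the plane of the two helix axes: the inter-axis angle
        # then changes by exactly the applied rotation
        normal = np.cross(ax_x, ax_y)
        normal /= np.linalg.norm(normal)
        R = Rotation.from_rotvec(np.radians(12.0) * normal).as_matrix()
        coords = free.coords.copy()
        cen = coords[idx].mean(axis=0)
        coords[idx] = (coords[idx] - cen) @ R.T + cen
        base = chz.inter_sse_angle_change(self._pair(free, coords), sx, sy)
        G = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        moved = coords @ G.T + rng.uniform(-40, 40, 3)
        assert chz.inter_sse_angle_change(self._pair(free, moved), sx, sy) == \
            pytest.approx(base, abs=1e-6)

    def test_symmetric_in_segment_order(self, helix_pair):
        free, (sx, sy) = helix_pair
        rng = np.random.default_rng(7)
        coords = free.coords + rng.normal(0, 0.3, free.coords.shape)
        pair = self._pair(free, coords)
        assert chz.inter_sse_angle_change(pair, sx, sy) == \
            pytest.approx(chz.inter_sse_angle_change(pair, sy, sx), abs=1e-9)

    def test_collinear_segment_raises(self):
        coords = np.column_stack([np.arange(9) * 3.8, np.zeros(9), np.zeros(9)])
        free = make_ca(coords)
        pair = self._pair(free, coords.copy())
        with pytest.raises(CharacterizeError, match="degenerate"):
            chz.inter_sse_angle_change(pair, SseSegment("H", 0, 3),
                                       SseSegment("H", 4, 8))


class TestActiveSiteDistance:
    def test_residue_at_centroid(self):
        s = make_ca([[0, 0, 0], [2, 0, 0], [-2, 0, 0], [0, 2, 0], [0, -2, 0]])
        d = chz.active_site_distance(s, [[1, 2, 3, 4]])
        assert d[0] == pytest.approx(0.0)

    def test_minimum_over_two_sites(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 40, (20, 3))
        s = make_ca(coords)
        sites = [[0, 1, 2], [15, 16]]
        d = chz.active_site_distance(s, sites)
        cents = [coords[site].mean(axis=0) for site in sites]
        for i in range(20):
            ref = min(np.linalg.norm(coords[i] - c) for c in cents)
            assert d[i] == pytest.approx(ref, rel=1e-12)

    def test_empty_site_raises(self):
        s = make_ca(np.eye(3))
        with pytest.raises(CharacterizeError):
            chz.active_site_distance(s, [[]])


class TestContactCounts:
    def test_counts_against_loop_oracle(self, tmp_path):
        spec = synthdata.FixtureSpec(seed=13, n_residues=24)
        s, _ = synthdata.make_structure(spec)
        path = tmp_path / "full.pdb"
        synthdata.write_structure_pdb(s, str(path), full_atom=True)
        s2 = structio.read_ca_structure(str(path))
        counts = chz.contact_counts(str(path), s2, cutoff=5.0)
        assert counts.sum() > 0
        # sequence neighbors are excluded
        s_iso = make_ca([[0, 0, 0], [3.8, 0, 0]])
        # no file-backed atoms: verify the exclusion rule on the fixture
        assert counts.max() <= len(s2) - 3 + 1


class TestRsa:
    def test_full_and_zero_accessibility(self):
        rsa, exposed = chz.rsa_from_acc(
            np.array([129.0, 0.0]), np.array(["ALA", "ALA"]))
        assert rsa[0] == pytest.approx(100.0)
        assert rsa[1] == pytest.approx(0.0)
        assert exposed[0] and not exposed[1]

    def test_gly_midrange_hand_division(self):
        rsa, _ = chz.rsa_from_acc(np.array([52.0]), np.array(["GLY"]))
        assert rsa[0] == pytest.approx(100.0 * 52.0 / 104.0)

    def test_unknown_residue_flagged_nan(self):
        rsa, _ = chz.rsa_from_acc(np.array([10.0]), np.array(["XYZ"]))
        assert np.isnan(rsa[0])


class TestCorrelates:
    def test_identical_vectors(self):
        x = np.arange(12, dtype=float)
        out = chz.residue_correlates(x, rsa=x)
        assert out["zscore_s_vs_rsa"]["pearson_r"] == pytest.approx(1.0)

    def test_anti_ranked_spearman(self):
        x = np.arange(12, dtype=float)
        out = chz.residue_correlates(x, rsa=x[::-1].copy())
        assert out["zscore_s_vs_rsa"]["spearman_rho"] == pytest.approx(-1.0)

    def test_planted_linear_relation_sign_recovered(self):
        rng = np.random.default_rng(17)
        z = rng.normal(size=120)
        rsa = 3.0 * z + rng.normal(0, 1.0, 120)
        contacts = -2.0 * z + rng.normal(0, 1.0, 120)
        out = chz.residue_correlates(z, rsa=rsa, contacts=contacts)
        assert out["zscore_s_vs_rsa"]["pearson_r"] > 0.5
        assert out["zscore_s_vs_contacts"]["pearson_r"] < -0.5

    def test_constant_vector_raises(self):
        with pytest.raises(CharacterizeError):
            chz.residue_correlates(np.ones(5), rsa=np.arange(5.0))


class TestDsspFile:
    @staticmethod
    def _dssp_line(index, resseq, chain, aa, ss, acc):
        line = [" "] * 120
        line[:5] = f"{index:5d}"
        line[5:10] = f"{resseq:5d}"
        line[11] = chain
        line[13] = aa
        line[16] = ss
        line[34:38] = f"{acc:4d}"
        # hydrogen-bond and torsion fields (unused here, format demands them)
        for start, stop, text in ((38, 45, "0"), (46, 50, "0.0"),
                                  (50, 56, "0"), (57, 61, "0.0"),
                                  (61, 67, "0"), (68, 72, "0.0"),
                                  (72, 78, "0"), (79, 83, "0.0")):
            line[start:stop] = f"{text:>{stop - start}}"
        line[103:109] = f"{-60.0:6.1f}"
        line[109:115] = f"{-45.0:6.1f}"
        return "".join(line)

    def _write_dssp(self, tmp_path, records):
        lines = ["==== Secondary Structure Definition (synthetic test file)",
                 "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    "
                 "O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI"]
        for i, (resseq, chain, aa, ss, acc) in enumerate(records, 1):
            lines.append(self._dssp_line(i, resseq, chain, aa, ss, acc))
        path = tmp_path / "toy.dssp"
        path.write_text("\n".join(lines) + "\n")
        return str(path)

    def test_read_dssp_letters_and_acc(self, tmp_path):
        path = self._write_dssp(tmp_path, [(1, "A", "A", "H", 64),
                                           (2, "A", "G", "E", 52),
                                           (3, "A", "V", " ", 0)])
        records = structio.read_dssp(path)
        assert [r[1] for r in records] == ["H", "E", "N"]
        assert [r[2] for r in records] == [64.0, 52.0, 0.0]

    def test_rsa_from_dssp_maps_onto_structure(self, tmp_path):
        path = self._write_dssp(tmp_path, [(1, "A", "A", "H", 64),
                                           (2, "A", "G", "E", 52),
                                           (3, "A", "V", "T", 0)])
        s = make_ca(np.eye(3) * 4.0, res_names=["ALA", "GLY", "VAL"])
        rsa, exposed, sse = chz.rsa_from_dssp(path, s)
        assert rsa[0] == pytest.approx(100.0 * 64 / 129.0)
        assert rsa[1] == pytest.approx(100.0 * 52 / 104.0)
        assert rsa[2] == pytest.approx(0.0)
        assert list(sse) == ["H", "E", "T"]
        assert exposed[0] and exposed[1] and not exposed[2]
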