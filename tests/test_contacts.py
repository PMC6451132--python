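"""Contact geometry: ring planes, halogen-pi / polar screens, superposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribofret import contacts as cg


def build_structure(atom_rows):
    """rows: (chain, res_name, res_id, atom_name, element, xyz)."""
    chain, rname, rid, aname, elem, xyz = zip(*atom_rows)
    return cg.Structure(
        chain_id=np.array(chain, dtype=str),
        res_name=np.array(rname, dtype=str),
        res_id=np.array(rid, dtype=int),
        atom_name=np.array(aname, dtype=str),
        element=np.array(elem, dtype=str),
        coord=np.array(xyz, dtype=float),
        occupancy=np.ones(len(xyz)),
    )


def hexagon(center, normal, radius=1.39, phase=0.0):
    """Six points of a regular hexagon in the plane orthogonal to ``normal``."""
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = phase + np.arange(6) * np.pi / 3
    return np.asarray(center) + radius * (np.outer(np.cos(ang), u)
                                          + np.outer(np.sin(ang), v))


def guanine_ring(chain, res_id, center, normal, **kw):
    pts = hexagon(center, normal, **kw)
    return [(chain, "G", res_id, name, name[0], p)
            for name, p in zip(cg.PURINE_SIX_RING, pts)]


def random_rotation(rng):
    q = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(q)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


class TestStructureIO:
    def test_minimal_pdb_round_trip(self, tmp_path):
        s = build_structure([
            ("A", "G", 1, "N1", "N", (0.0, 0.0, 0.0)),
            ("A", "G", 1, "C2", "C", (1.5, 0.0, 0.0)),
            ("A", "G", 1, "N3", "N", (0.0, 1.5, 0.0)),
        ])
        path = tmp_path / "mini.pdb"
        cg.write_structure_pdb(s, path)
        back = cg.load_structure(path)
        assert len(back) == 3
        assert np.allclose(back.coord, s.coord, atol=1e-3)  # PDB precision

    def test_altloc_resolved_by_occupancy(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1      10.000  10.000  10.000  0.40 10.00           C\n"
            "ATOM      2  CA BALA A   1      20.000  20.000  20.000  0.60 10.00           C\n"
            "END\n")
        path = tmp_path / "altloc.pdb"
        path.write_text(text)
        s = cg.load_structure(path)
        assert len(s) == 1
        assert np.allclose(s.coord[0], [20.0, 20.0, 20.0])

    def test_selection_syntax(self):
        sel = cg.parse_selection("A:2001:CL1")
        assert sel == {"chain_id": "A", "res_id": 2001, "atom_name": "CL1"}


class TestRingCentroidNormal:
    def test_regular_hexagon_in_xy_plane(self):
        s = build_structure(guanine_ring("A", 1, (0, 0, 0), (0, 0, 1)))
        centroid, normal = cg.ring_centroid_normal(s, cg.RingSpec("A", 1))
        assert np.allclose(centroid, 0.0, atol=1e-12)
        assert abs(abs(normal[2]) - 1.0) < 1e-12

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(0)
        R = random_rotation(rng)
        shift = np.array([5.0, -3.0, 2.0])
        base = hexagon((0, 0, 0), (0, 0, 1), phase=0.3)
        rows0 = [("A", "G", 1, n, n[0], p)
                 for n, p in zip(cg.PURINE_SIX_RING, base)]
        rows1 = [("A", "G", 1, n, n[0], R @ p + shift)
                 for n, p in zip(cg.PURINE_SIX_RING, base)]
        c0, n0 = cg.ring_centroid_normal(build_structure(rows0),
                                         cg.RingSpec("A", 1))
        c1, n1 = cg.ring_centroid_normal(build_structure(rows1),
                                         cg.RingSpec("A", 1))
        assert np.allclose(c1, R @ c0 + shift, atol=1e-9)
        assert abs(abs(np.dot(n1, R @ n0)) - 1.0) < 1e-9

    def test_puckered_ring_matches_plane_fit(self):
        # 0.1 A out-of-plane noise: normal within 5 deg of z and of an
        # independent least-squares plane fit (z = ax + by + c)
        rng = np.random.default_rng(1)
        pts = hexagon((0, 0, 0), (0, 0, 1))
        pts[:, 2] += rng.normal(0, 0.1, 6)
        rows = [("A", "G", 1, n, n[0], p)
                for n, p in zip(cg.PURINE_SIX_RING, pts)]
        _, normal = cg.ring_centroid_normal(build_structure(rows),
                                            cg.RingSpec("A", 1))
        assert np.degrees(np.arccos(abs(normal[2]))) < 5.0
        A = np.c_[pts[:, 0], pts[:, 1], np.ones(6)]
        (a, b, _), *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
        fit_normal = np.array([-a, -b, 1.0])
        fit_normal /= np.linalg.norm(fit_normal)
        assert abs(abs(np.dot(normal, fit_normal)) - 1.0) < 1e-3

    def test_ring_choice_distances_flags_ambiguity(self):
        # a full purine: five-membered ring centroid sits ~2.4 A from the
        # six-membered one, so a probe over the six-ring is ambiguous
        six = hexagon((0, 0, 0), (0, 0, 1), phase=np.pi / 6)
        rows = [("A", "G", 1, n, n[0], p)
                for n, p in zip(cg.PURINE_SIX_RING, six)]
        # crude imidazole completion off C4/C5
        for name, p in (("N7", (2.4, 1.2, 0.0)), ("C8", (3.3, 0.2, 0.0)),
                        ("N9", (2.6, -1.0, 0.0))):
            rows.append(("A", "G", 1, name, name[0], p))
        s = build_structure(rows)
        out = cg.ring_choice_distances(s, "A", 1, np.array([0.0, 0.0, 3.4]))
        assert out["six"] == pytest.approx(3.4, abs=1e-9)
        assert out["ambiguous"]
        assert out["five"] > out["six"]

    def test_missing_atom_named_in_error(self):
        rows = guanine_ring("A", 1, (0, 0, 0), (0, 0, 1))[:-1]  # drop C6
        with pytest.raises(ValueError, match="C6"):
            cg.ring_centroid_normal(build_structure(rows), cg.RingSpec("A", 1))


class TestHalogenPi:
    def pocket_with_cl(self, offset_along_normal=3.4, in_plane=False):
        rows = guanine_ring("A", 2793, (0, 0, 0), (0, 0, 1))
        pos = ((3.4, 0, 0) if in_plane
               else (0, 0, offset_along_normal))
        rows.append(("B", "LIG", 1, "CL2", "CL", pos))
        return build_structure(rows)

    def test_face_on_contact(self):
        s = self.pocket_with_cl()
        found = cg.find_halogen_pi(s, {"chain_id": "B", "res_id": 1})
        assert len(found) == 1
        c = found[0]
        assert c.distance == pytest.approx(3.4, abs=1e-12)
        assert c.angle == pytest.approx(0.0, abs=1e-9)
        assert c.face_on and c.geometry == "face-on"

    def test_edge_on_not_face_on(self):
        s = self.pocket_with_cl(in_plane=True)
        c = cg.find_halogen_pi(s, {"chain_id": "B", "res_id": 1})[0]
        assert c.angle == pytest.approx(90.0, abs=1e-9)
        assert not c.face_on

    def test_no_halogens_warns_empty(self):
        rows = guanine_ring("A", 1, (0, 0, 0), (0, 0, 1))
        rows.append(("B", "LIG", 1, "C1", "C", (0, 0, 3.0)))
        s = build_structure(rows)
        with pytest.warns(UserWarning, match="no halogen"):
            assert cg.find_halogen_pi(s, {"chain_id": "B"}) == []

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 100_000))
    def test_matches_brute_force_on_random_pockets(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        rings = []
        for k in range(4):
            center = rng.uniform(-6, 6, 3)
            normal = rng.normal(size=3)
            normal /= np.linalg.norm(normal)
            pts = hexagon(center, normal, phase=rng.uniform(0, np.pi))
            pts += rng.normal(0, 0.02, pts.shape)  # slight pucker
            rows += [("A", "G", k + 1, n, n[0], p)
                     for n, p in zip(cg.PURINE_SIX_RING, pts)]
            rings.append((k + 1, pts))
        halogens = rng.uniform(-6, 6, (3, 3))
        rows += [("B", "LIG", 99, f"CL{i}", "CL", h)
                 for i, h in enumerate(halogens)]
        s = build_structure(rows)
        found = cg.find_halogen_pi(s, {"chain_id": "B"}, max_distance=5.0)
        # O(n^2) oracle; the normal comes from an independent construction
        # (summed edge cross products), so angles agree only up to the
        # plane-estimator difference on puckered rings
        expected = {}
        for res_id, pts in rings:
            centroid = pts.mean(axis=0)
            cross = np.zeros(3)
            for i in range(6):
                cross += np.cross(pts[i] - centroid,
                                  pts[(i + 1) % 6] - centroid)
            n_hat = cross / np.linalg.norm(cross)
            for i, h in enumerate(halogens):
                v = h - centroid
                d = np.linalg.norm(v)
                if 0 < d <= 5.0:
                    ang = np.degrees(np.arccos(
                        np.clip(abs(np.dot(v / d, n_hat)), 0, 1)))
                    expected[(f"CL{i}", res_id)] = (d, ang)
        got = {(c.halogen.atom_name, c.ring_residue.res_id):
               (c.distance, c.angle) for c in found}
        assert set(got) == set(expected)
        for key, (d, ang) in expected.items():
            assert got[key][0] == pytest.approx(d, abs=1e-9)
            assert got[key][1] == pytest.approx(ang, abs=0.2)

    def test_sorted_by_distance(self):
        rows = guanine_ring("A", 1, (0, 0, 0), (0, 0, 1))
        rows += guanine_ring("A", 2, (10, 0, 0), (0, 0, 1))
        rows.append(("B", "LIG", 9, "CL1", "CL", (10, 0, 3.0)))
        rows.append(("B", "LIG", 9, "CL2", "CL", (0, 0, 4.0)))
        found = cg.find_halogen_pi(build_structure(rows), {"chain_id": "B"})
        assert [c.distance for c in found] == sorted(c.distance for c in found)


class TestPolarContacts:
    def test_chlorine_to_base_nitrogen(self):
        rows = [("A", "C", 2764, "N4", "N", (0.0, 0.0, 0.0)),
                ("B", "LIG", 1, "CL1", "CL", (3.2, 0.0, 0.0))]
        found = cg.find_polar_contacts(build_structure(rows), {"chain_id": "B"})
        assert len(found) == 1
        assert found[0].distance == pytest.approx(3.2, abs=1e-12)
        assert found[0].contact_class == "Cl...base"

    def test_cutoff_boundary_excludes(self):
        rows = [("A", "C", 1, "N4", "N", (0.0, 0.0, 0.0)),
                ("B", "LIG", 1, "O7", "O", (3.7, 0.0, 0.0))]
        assert cg.find_polar_contacts(build_structure(rows),
                                      {"chain_id": "B"}) == []

    def test_oxygen_classes(self):
        rows = [("A", "PRO", 56, "N", "N", (0.0, 0.0, 0.0)),
                ("A", "PHE", 58, "O", "O", (2.9, 3.0, 0.0)),
                ("B", "LIG", 1, "O7", "O", (2.9, 0.0, 0.0))]
        found = cg.find_polar_contacts(build_structure(rows), {"chain_id": "B"})
        classes = {c.contact_class for c in found}
        assert classes == {"O...H-N", "O...H-O"}

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 100_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        elements = ["N", "O", "C"]
        rows = [("A", "RES", i, f"X{i}", elements[i % 3],
                 rng.uniform(-8, 8, 3)) for i in range(25)]
        rows += [("B", "LIG", 99, name, el, rng.uniform(-8, 8, 3))
                 for name, el in (("CL1", "CL"), ("O7", "O"), ("C9", "C"))]
        s = build_structure(rows)
        found = cg.find_polar_contacts(s, {"chain_id": "B"}, max_distance=4.0)
        expected = set()
        for i in range(len(s)):
            if s.chain_id[i] != "B" or s.element[i] not in ("CL", "O"):
                continue
            for j in range(len(s)):
                if s.chain_id[j] == "B" or s.element[j] not in ("N", "O"):
                    continue
                d = np.linalg.norm(s.coord[i] - s.coord[j])
                if 0 < d <= 4.0:
                    expected.add((s.atom_name[i], s.atom_name[j], round(d, 9)))
        got = {(c.ligand_atom.atom_name, c.partner_atom.atom_name,
                round(c.distance, 9)) for c in found}
        assert got == expected


class TestSuperposeRMSD:
    def test_identical_sets(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(10, 3))
        rmsd, R, t = cg.superpose_rmsd(A, A)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(15, 3))
        R = random_rotation(rng)
        B = A @ R.T + np.array([1.0, -2.0, 3.0])
        rmsd, Rhat, that = cg.superpose_rmsd(A, B)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(Rhat @ B.T + that[:, None], A.T, atol=1e-9)

    def test_noise_rmsd_matches_expectation(self):
        # B = A + N(0, sigma): after removing the 6 rigid-body dof,
        # E[RMSD^2] = sigma^2 (3n - 6) / n
        rng = np.random.default_rng(4)
        n, sigma = 10, 0.3
        rmsds = []
        for _ in range(200):
            A = rng.normal(size=(n, 3)) * 3.0
            B = A + rng.normal(0, sigma, size=(n, 3))
            rmsds.append(cg.superpose_rmsd(A, B)[0])
        expected = sigma * np.sqrt((3 * n - 6) / n)
        assert np.mean(rmsds) == pytest.approx(expected, rel=0.10)

    def test_cross_check_against_biopython(self):
        from Bio.SVDSuperimposer import SVDSuperimposer

        rng = np.random.default_rng(5)
        A = rng.normal(size=(12, 3)) * 4
        B = A @ random_rotation(rng).T + 2.0 + rng.normal(0, 0.5, (12, 3))
        rmsd, _, _ = cg.superpose_rmsd(A, B)
        sup = SVDSuperimposer()
        sup.set(A, B)
        sup.run()
        assert rmsd == pytest.approx(sup.get_rms(), rel=1e-9)

    def test_collinear_raises(self):
        A = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError, match="collinear"):
            cg.superpose_rmsd(A, A)

    def test_invariance_of_contact_geometry_under_rigid_motion(self):
        # distances/angles reported by the halogen-pi finder are unchanged
        # when the whole structure is rigidly moved
        rng = np.random.default_rng(6)
        rows = guanine_ring("A", 1, (0, 0, 0), (0.3, 0.2, 1.0))
        rows.append(("B", "LIG", 1, "CL1", "CL", (0.5, 0.3, 3.0)))
        s0 = build_structure(rows)
        R = random_rotation(rng)
        shift = rng.normal(size=3) * 10
        s1 = build_structure([
            (c, rn, ri, an, el, R @ np.asarray(p) + shift)
            for (c, rn, ri, an, el, p) in rows])
        c0 = cg.find_halogen_pi(s0, {"chain_id": "B"})[0]
        c1 = cg.find_halogen_pi(s1, {"chain_id": "B"})[0]
        assert c1.distance == pytest.approx(c0.distance, rel=1e-9)
        assert c1.angle == pytest.approx(c0.angle, abs=1e-6)
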