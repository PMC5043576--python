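"""Geometric primitives: dihedrals, superposition, SASA, chain building."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from igtandem import (DegenerateGeometryError, DihedralUndefinedError,
                      build_chain, dihedral, kabsch_superpose, phi_psi,
                      shrake_rupley_sasa)
from igtandem.geometry import golden_spiral, wrap_angle


def oracle_dihedral(p1, p2, p3, p4):
    """Independent formulation: project the outer bonds onto the plane
    perpendicular to the central bond and measure the signed angle."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b = p3 - p2
    b = b / np.linalg.norm(b)
    u = (p1 - p2) - ((p1 - p2) @ b) * b
    v = (p4 - p3) - ((p4 - p3) @ b) * b
    x = u @ v
    y = np.cross(u, v) @ b
    return wrap_angle(np.degrees(np.arctan2(y, x)))


class TestDihedral:
    def test_planar_cases(self):
        assert dihedral([1, 1, 0], [1, 0, 0], [0, 0, 0],
                        [-1, 1, 0]) == pytest.approx(0.0, abs=1e-12)
        assert abs(dihedral([1, 1, 0], [1, 0, 0], [0, 0, 0],
                            [-1, -1, 0])) == pytest.approx(180.0)

    def test_matches_independent_oracle(self, rng):
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                ours = dihedral(*pts)
            except DihedralUndefinedError:
                continue
            assert ours == pytest.approx(oracle_dihedral(*pts), abs=1e-9)

    def test_rigid_transform_invariance(self, rng):
        pts = rng.normal(size=(4, 3)) * 2
        ref = dihedral(*pts)
        for _ in range(100):
            r = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(size=3) * 10
            moved = pts @ r.T + t
            assert dihedral(*moved) == pytest.approx(ref, abs=1e-8)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DihedralUndefinedError):
            dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
        with pytest.raises(DihedralUndefinedError):
            dihedral([2, 0, 0], [1, 0, 0], [0, 0, 0], [-1, 0, 0])


class TestPhiPsi:
    def test_ideal_helix_angles(self):
        st = build_chain([("ALA", -57.0, -47.0, 180.0)] * 8)
        t = phi_psi(st, "A")
        interior = t.iloc[1:-1]
        np.testing.assert_allclose(interior["phi"], -57.0, atol=1.0)
        np.testing.assert_allclose(interior["psi"], -47.0, atol=1.0)

    def test_termini_missing(self):
        st = build_chain([("ALA", -60.0, -40.0, 180.0)] * 4)
        t = phi_psi(st, "A")
        assert np.isnan(t.iloc[0]["phi"]) and np.isnan(t.iloc[-1]["psi"])

    def test_chain_break_yields_missing(self):
        st = build_chain([("ALA", -60.0, -40.0, 180.0)] * 6)
        # translate the last three residues far away -> C-N > 2 A at 3|4
        for r in st.residues("A")[3:]:
            for a in r.atoms:
                a.coords = a.coords + np.array([50.0, 0.0, 0.0])
        t = phi_psi(st, "A")
        assert np.isnan(t.iloc[3]["phi"])
        assert np.isnan(t.iloc[2]["psi"])
        assert not np.isnan(t.iloc[2]["phi"])


def oracle_grid_rmsd(mobile, target, coarse=15, fine=1):
    """Hierarchical rotation-grid search (down to a 1-degree grid) for the
    minimal rmsd over proper rotations; centering removes translation."""
    a = mobile - mobile.mean(axis=0)
    b = target - target.mean(axis=0)

    def best_on(grids):
        angles = np.stack(np.meshgrid(*grids, indexing="ij"), -1).reshape(-1, 3)
        mats = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
        rot = np.einsum("rij,nj->rni", mats, a)
        rmsds = np.sqrt(((rot - b) ** 2).sum(-1).mean(-1))
        k = int(np.argmin(rmsds))
        return angles[k], float(rmsds[k])

    span = np.arange(0, 360, coarse)
    half = np.arange(0, 180 + coarse, coarse)
    center, _ = best_on((span, half, span))
    fine_grids = tuple(np.arange(c - coarse, c + coarse + fine, fine)
                       for c in center)
    _, rmsd = best_on(fine_grids)
    return rmsd


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(size=(6, 3))
        s = kabsch_superpose(pts, pts)
        assert s.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(s.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_transform(self, rng):
        pts = rng.normal(size=(8, 3))
        r = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        moved = pts @ r.T + np.array([1.0, -2.0, 3.0])
        s = kabsch_superpose(pts, moved)
        assert s.rmsd < 1e-9
        np.testing.assert_allclose(s.rotation, r, atol=1e-9)
        np.testing.assert_allclose(s.apply(pts), moved, atol=1e-9)
        assert np.linalg.det(s.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_symmetric(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(b, a).rmsd, abs=1e-9)

    def test_matches_rotation_grid_oracle(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        ours = kabsch_superpose(a, b).rmsd
        oracle = oracle_grid_rmsd(a, b)
        assert ours <= oracle + 1e-9  # optimality
        assert oracle - ours < 0.05   # grid resolution slack

    def test_degenerate_inputs_raise(self, rng):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line + 1.0)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        for el, r in (("C", 1.70), ("O", 1.52)):
            area = shrake_rupley_sasa((np.zeros((1, 3)), [el]))[0]
            exact = 4 * np.pi * (r + 1.4) ** 2
            assert area == pytest.approx(exact, rel=0.01)

    def test_far_separated_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        areas = shrake_rupley_sasa((coords, ["C", "C"]))
        single = shrake_rupley_sasa((np.zeros((1, 3)), ["C"]))[0]
        np.testing.assert_allclose(areas, single, rtol=1e-12)

    def test_overlap_matches_high_density_reference(self):
        coords = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        fast = shrake_rupley_sasa((coords, ["C", "N"]), n_points=960)
        dense = shrake_rupley_sasa((coords, ["C", "N"]), n_points=100_000)
        np.testing.assert_allclose(fast, dense, rtol=0.02)

    def test_monotone_decrease_on_approach(self):
        prev = np.inf
        for d in np.arange(6.5, 1.0, -0.5):
            total = shrake_rupley_sasa(
                (np.array([[0.0, 0, 0], [d, 0, 0]]), ["C", "C"])).sum()
            assert total <= prev + 1e-9
            prev = total

    def test_unknown_element_raises(self):
        with pytest.raises(KeyError):
            shrake_rupley_sasa((np.zeros((1, 3)), ["Xx"]))

    def test_matches_mdtraj_oracle(self):
        mdtraj = pytest.importorskip("mdtraj")
        import mdtraj.core.element as elem

        coords = np.array([[0.0, 0.0, 0.0], [1.9, 0.8, 0.0],
                           [3.1, -0.5, 1.0], [0.5, 2.8, -0.7]])
        elements = ["C", "N", "O", "C"]
        top = mdtraj.Topology()
        ch = top.add_chain()
        res = top.add_residue("UNK", ch)
        for i, e in enumerate(elements):
            top.add_atom(f"X{i}", elem.get_by_symbol(e), res)
        traj = mdtraj.Trajectory(coords[None] / 10.0, top)  # nm
        ref = mdtraj.shrake_rupley(traj, n_sphere_points=960)[0] * 100.0
        ours = shrake_rupley_sasa((coords, elements))
        np.testing.assert_allclose(ours, ref, rtol=0.03)

    def test_golden_spiral_is_deterministic_unit_lattice(self):
        pts = golden_spiral(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_array_equal(pts, golden_spiral(960))


class TestBuildChain:
    def test_round_trip_random_specs(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            spec = [("ALA", rng.uniform(-170, -40), rng.uniform(-60, 160),
                     180.0) for _ in range(n)]
            st = build_chain(spec)
            t = phi_psi(st, "A")
            for i in range(1, n):
                assert t.iloc[i]["phi"] == pytest.approx(spec[i][1], abs=0.5)
            for i in range(n - 1):
                assert t.iloc[i]["psi"] == pytest.approx(spec[i][2], abs=0.5)

    def test_type_ii_turn_fixture_is_detected(self):
        from igtandem import detect_turns

        strand = ("ALA", -120.0, 130.0, 180.0)
        spec = [strand, strand,
                ("ALA", -60.0, 120.0, 180.0), ("GLY", 80.0, 0.0, 180.0),
                strand, strand]
        found = detect_turns(build_chain(spec))
        assert any(t.type == "II" for t in found)

    def test_empty_and_unknown_residue_raise(self):
        with pytest.raises(ValueError):
            build_chain([])
        with pytest.raises(ValueError):
            build_chain([("XYZ", -60, -40, 180)])

    def test_gly_has_no_cb(self):
        st = build_chain([("GLY", -60, -40, 180), ("ALA", -60, -40, 180)])
        assert st.residues("A")[0].atom("CB") is None
        assert st.residues("A")[1].atom("CB") is not None
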