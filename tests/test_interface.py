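"""Hydrogen bonds, contacts, burial and interdomain geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from igtandem import (DegenerateGeometryError, IgtandemError, build_chain,
                      burial_fraction, find_hbonds, interdomain_geometry,
                      interface_contacts, pole_charges)
from igtandem.geometry import transform_structure
from igtandem.interface import (SIDECHAIN_ACCEPTORS, SIDECHAIN_DONORS,
                                interdomain_geometry_ca, principal_axis)
from igtandem.structure import Atom, DomainSplit, Residue, Structure
from igtandem.synthetic import gen_ig_tandem


def oracle_hbonds(structure, d_max=3.5, ang_min=120.0):
    """Brute-force all-pairs enumeration with explicit loops."""
    residues = []
    for chain in structure.chains():
        residues.extend((chain, i, r)
                        for i, r in enumerate(structure.residues(chain)))
    found = set()
    for dc, di, dres in residues:
        donor_atoms = []
        if dres.atom("N") is not None and dres.aa3 != "PRO":
            donor_atoms.append((dres.atom("N"), dres.atom("CA"), True))
        for name, ante in SIDECHAIN_DONORS.get(dres.aa3, {}).items():
            if dres.atom(name) is not None:
                donor_atoms.append((dres.atom(name), dres.atom(ante), False))
        for ac, ai, ares in residues:
            if (dc, di) == (ac, ai):
                continue
            acc_atoms = [(ares.atom(n), True) for n in ("O", "OXT")
                         if ares.atom(n) is not None]
            acc_atoms += [(ares.atom(n), False)
                          for n in SIDECHAIN_ACCEPTORS.get(ares.aa3, ())
                          if ares.atom(n) is not None]
            for datom, ante, d_bb in donor_atoms:
                for aatom, a_bb in acc_atoms:
                    if d_bb and a_bb and dc == ac and abs(di - ai) < 2:
                        continue
                    dist = np.linalg.norm(datom.coords - aatom.coords)
                    if dist > d_max:
                        continue
                    if ante is not None:
                        v1 = ante.coords - datom.coords
                        v2 = aatom.coords - datom.coords
                        ang = np.degrees(np.arccos(np.clip(
                            v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2),
                            -1, 1)))
                        if ang < ang_min:
                            continue
                    found.add((dres.key, datom.name, ares.key, aatom.name))
    return found


def _thr_with_acceptor(og1_to_o=2.4):
    """A Thr whose hydroxyl points at a carbonyl O of another residue."""
    thr = Residue("A", 1, "", "THR", [
        Atom("N", "N", [0.0, 3.0, 0.0]),
        Atom("CA", "C", [0.0, 1.5, 0.0]),
        Atom("C", "C", [1.4, 0.9, 0.0]),
        Atom("O", "O", [2.4, 1.6, 0.0]),
        Atom("CB", "C", [-1.2, 0.6, 0.0]),
        Atom("OG1", "O", [-1.2 + 1.4, 0.6 - 0.4, 0.0]),
    ])
    og1 = thr.atom("OG1").coords
    direction = np.array([1.0, -0.3, 0.0])
    direction /= np.linalg.norm(direction)
    partner = Residue("A", 10, "", "ALA", [
        Atom("C", "C", og1 + (og1_to_o + 1.23) * direction),
        Atom("O", "O", og1 + og1_to_o * direction),
    ])
    return Structure([{"A": [thr, partner]}])


class TestHbonds:
    def test_tight_thr_hydroxyl_bond(self):
        st = _thr_with_acceptor(2.4)
        bonds = [b for b in find_hbonds(st) if b.donor[3] == "OG1"]
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.4, abs=1e-6)
        assert bonds[0].acceptor[3] == "O"

    def test_long_distance_rejected(self):
        st = _thr_with_acceptor(4.0)
        assert [b for b in find_hbonds(st) if b.donor[3] == "OG1"] == []

    def test_matches_brute_force_enumeration(self):
        spec = [("SER", -60.0, -30.0, 180.0), ("ALA", -90.0, 0.0, 180.0),
                ("THR", 60.0, 30.0, 180.0), ("GLY", -120.0, 130.0, 180.0),
                ("ASN", -60.0, 120.0, 180.0)]
        st = build_chain(spec)
        ours = {(b.donor[0], b.donor[1], b.donor[3],
                 b.acceptor[0], b.acceptor[1], b.acceptor[3])
                for b in find_hbonds(st)}
        oracle = {((d[0]), d[1], dn, a[0], a[1], an)
                  for d, dn, a, an in oracle_hbonds(st)}
        assert ours == oracle

    def test_invariant_under_rigid_transform(self, rng):
        st = _thr_with_acceptor(2.8)
        ref = [(b.donor, b.acceptor, round(b.distance, 6))
               for b in find_hbonds(st)]
        r = Rotation.random(random_state=rng).as_matrix()
        moved = transform_structure(st, r, rng.normal(size=3) * 20)
        got = [(b.donor, b.acceptor, round(b.distance, 6))
               for b in find_hbonds(moved)]
        assert got == ref

    def test_sorted_by_distance(self, tandem):
        bonds = find_hbonds(tandem)
        dists = [b.distance for b in bonds]
        assert dists == sorted(dists)


def _two_blob_structure(separation):
    """Two tiny 'domains' of carbon-only residues at a set separation."""

    def blob(start_num, offset):
        out = []
        for i in range(2):
            coords = np.array([0.0, 5.0 * i, 0.0]) + offset
            out.append(Residue("A", start_num + i, "", "ALA",
                               [Atom("CA", "C", coords),
                                Atom("CB", "C", coords + [1.0, 0, 0])]))
        return out
    residues = blob(1, np.zeros(3)) + blob(10, np.array([separation, 0, 0]))
    split = DomainSplit({"d1": ("A", 1, 2), "d2": ("A", 10, 11)})
    return Structure([{"A": residues}]), split


class TestContacts:
    def test_far_domains_empty(self):
        st, split = _two_blob_structure(50.0)
        assert interface_contacts(st, split) == []

    def test_engineered_pair_found(self):
        st, split = _two_blob_structure(50.0)
        # engineer one 3.5 A cross-domain pair: CB(res 1) ... CA(res 10)
        st.models[0]["A"][2].atom("CA").coords = np.array([4.5, 0.0, 0.0])
        contacts = interface_contacts(st, split)
        assert [(c.residue_a[1], c.residue_b[1]) for c in contacts] == [(1, 10)]
        assert contacts[0].min_distance == pytest.approx(3.5)

    def test_tandem_interface_has_contacts(self, tandem, tandem_split):
        contacts = interface_contacts(tandem, tandem_split)
        assert contacts
        for c in contacts:
            assert c.min_distance <= 4.0
            assert 1 <= c.residue_a[1] <= 90 and 93 <= c.residue_b[1] <= 182

    def test_count_matches_brute_force(self, tandem, tandem_split):
        contacts = interface_contacts(tandem, tandem_split, cutoff=5.0)
        res_a = tandem_split.residues_of(tandem, "I10")
        res_b = tandem_split.residues_of(tandem, "I11")
        brute = set()
        for ra in res_a:
            for rb in res_b:
                d = min(np.linalg.norm(x.coords - y.coords)
                        for x in ra.atoms for y in rb.atoms)
                if d <= 5.0:
                    brute.add((ra.number, rb.number))
        assert {(c.residue_a[1], c.residue_b[1]) for c in contacts} == brute

    def test_missing_split_range_errors(self, tandem):
        bad = DomainSplit({"a": ("A", 1, 90), "b": ("A", 500, 600)})
        with pytest.raises(IgtandemError):
            interface_contacts(tandem, bad)


class TestBurial:
    def test_surface_residue_near_zero(self, tandem, tandem_split):
        # residue in the middle of domain A's outer strand, far from the
        # interface with domain B
        frac = burial_fraction(tandem, tandem_split, ("A", 45))
        assert frac < 0.15

    def test_enclosed_residue_near_one(self):
        probe = Residue("A", 1, "", "ALA", [
            Atom("N", "N", [0.0, 0.0, 3.0]), Atom("CA", "C", [0.0, 0.0, 1.5]),
            Atom("C", "C", [1.4, 0.0, 1.0]), Atom("O", "O", [2.2, 0.0, 1.8]),
            Atom("CB", "C", [0.0, 0.0, 0.0])])
        from igtandem.geometry import golden_spiral

        cage = [Residue("A", 10 + i, "", "GLY", [Atom("CA", "C", p)])
                for i, p in enumerate(4.0 * golden_spiral(80))]
        st = Structure([{"A": [probe] + cage}])
        split = DomainSplit({"d1": ("A", 1, 1), "d2": ("A", 10, 89)})
        assert burial_fraction(st, split, ("A", 1)) > 0.85

    def test_gly_raises(self):
        st, split = _two_blob_structure(20.0)
        st.models[0]["A"][0] = Residue("A", 1, "", "GLY",
                                       [Atom("CA", "C", [0, 0, 0])])
        with pytest.raises(IgtandemError, match="no side-chain"):
            burial_fraction(st, split, ("A", 1))

    def test_monotone_under_approach(self):
        # burial grows (weakly) as the partner blob closes in on the probe
        fracs = []
        for sep in (20.0, 8.0, 5.0, 3.5):
            st, split = _two_blob_structure(sep)
            fracs.append(burial_fraction(st, split, ("A", 1)))
        assert all(b >= a - 1e-9 for a, b in zip(fracs, fracs[1:]))


class TestInterdomainGeometry:
    @pytest.mark.parametrize("twist", [20.0, 60.0, 100.0, 150.0, 180.0])
    def test_twist_sweep_recovery(self, twist):
        from igtandem.geometry import wrap_angle

        st = gen_ig_tandem(twist=twist, seed=2)
        geom = interdomain_geometry(st, st.metadata["split"])
        assert abs(wrap_angle(geom.torsion - twist)) <= 2.0

    def test_zero_twist_collinear(self):
        st = gen_ig_tandem(seed=2)
        geom = interdomain_geometry(st, st.metadata["split"])
        assert abs(geom.torsion) < 2.0
        assert geom.bend < 2.0

    def test_planted_bend(self):
        st = gen_ig_tandem(bend=30.0, seed=2)
        geom = interdomain_geometry(st, st.metadata["split"])
        assert geom.bend == pytest.approx(30.0, abs=2.0)

    def test_spherical_domain_errors(self, rng):
        ball = rng.normal(size=(40, 3))
        with pytest.raises(DegenerateGeometryError):
            principal_axis(ball)
        rod = np.column_stack([np.linspace(0, 30, 40),
                               rng.normal(scale=0.5, size=40),
                               rng.normal(scale=0.5, size=40)])
        with pytest.raises(DegenerateGeometryError):
            interdomain_geometry_ca(ball, rod)

    def test_too_few_ca_errors(self, tandem):
        small = DomainSplit({"a": ("A", 1, 5), "b": ("A", 93, 182)})
        with pytest.raises(IgtandemError, match="Calpha"):
            interdomain_geometry(tandem, small)


class TestPoleCharges:
    def test_charged_poles_sign_pattern(self, tandem, tandem_split):
        poles = pole_charges(tandem, tandem_split)
        for name in ("I10", "I11"):
            npole, cpole = poles[name]
            assert npole == 3 and cpole == -3  # 3 Lys / 3 Glu planted

    def test_neutral_polyala_domain(self):
        st = gen_ig_tandem(seed=5, charged_poles=False)
        poles = pole_charges(st, st.metadata["split"])
        assert poles["I10"] == (0, 0) and poles["I11"] == (0, 0)
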