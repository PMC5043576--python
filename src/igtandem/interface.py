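"""Hydrogen bonds, interdomain contacts, side-chain burial, tandem
torsion/bend geometry and pole-charge summaries for Ig-tandem structures.

The hydrogen-bond criterion is purely geometric (heavy atoms only): a
donor-acceptor distance cutoff plus an antecedent-donor-acceptor angle
check approximating donor-H linearity. Burial is SASA-based: the fraction
of side-chain surface lost when the residue's own domain is placed in the
full tandem. Interdomain geometry uses each domain's first principal axis
of its Calpha cloud (oriented N->C): torsion is the dihedral through the
axis tips around the inter-centroid line, bend the angle between the axes,
rise the centroid separation. This is one convention among several in the
tandem-orientation literature; absolute torsion values from other tools may
differ systematically even when trends agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, IgtandemError, SelectionError
from .geometry import dihedral, shrake_rupley_sasa
from .structure import BACKBONE_ATOMS, DomainSplit, Structure

# Heavy-atom donor table: atom name -> antecedent atom used for the angle
# check. Backbone N applies to every residue type.
SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "LYS": {"NZ": "CE"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "TRP": {"NE1": "CD1"},
}

SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}

FORMAL_CHARGE = {"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1, "HIS": 0}


@dataclass
class HBond:
    donor: tuple[str, int, str, str]     # chain, resnum, aa3, atom name
    acceptor: tuple[str, int, str, str]
    distance: float
    donor_angle: float | None  # antecedent-donor-acceptor angle, deg


def _enumerate_donors(structure: Structure, model: int):
    for chain in structure.chains(model):
        for seq_pos, r in enumerate(structure.residues(chain, model)):
            n = r.atom("N")
            if n is not None and r.aa3 != "PRO":
                yield r, seq_pos, n, r.atom("CA"), True
            for name, ante in SIDECHAIN_DONORS.get(r.aa3, {}).items():
                a = r.atom(name)
                if a is not None:
                    yield r, seq_pos, a, r.atom(ante), False


def _enumerate_acceptors(structure: Structure, model: int):
    for chain in structure.chains(model):
        for seq_pos, r in enumerate(structure.residues(chain, model)):
            for name in ("O", "OXT"):
                a = r.atom(name)
                if a is not None:
                    yield r, seq_pos, a, True
            for name in SIDECHAIN_ACCEPTORS.get(r.aa3, ()):
                a = r.atom(name)
                if a is not None:
                    yield r, seq_pos, a, False
            if r.aa3 in ("HOH", "WAT"):
                a = r.atom("O") or (r.atoms[0] if r.atoms else None)
                if a is not None and a.name not in ("O", "OXT"):
                    yield r, seq_pos, a, False


def find_hbonds(structure: Structure, d_max: float = 3.5,
                ang_min: float = 120.0, model: int = 0) -> list[HBond]:
    """Enumerate geometric hydrogen bonds (heavy-atom criterion).

    Donors are backbone amides (except Pro) and side-chain N/O of
    S,T,Y,K,R,N,Q,H,W; acceptors are carbonyl/carboxyl/hydroxyl oxygens and
    His ring nitrogens. A pair qualifies at distance <= ``d_max`` with
    antecedent-donor-acceptor angle >= ``ang_min`` (skipped when the
    antecedent atom is absent). Backbone-backbone pairs closer than 2
    positions in sequence are excluded; results are sorted by distance.
    """
    donors = list(_enumerate_donors(structure, model))
    acceptors = list(_enumerate_acceptors(structure, model))
    if not donors or not acceptors:
        return []
    acc_coords = np.array([a.coords for _r, _s, a, _bb in acceptors])
    tree = cKDTree(acc_coords)
    bonds: list[HBond] = []
    for dres, dpos, datom, ante, d_is_bb in donors:
        for j in tree.query_ball_point(datom.coords, d_max):
            ares, apos, aatom, a_is_bb = acceptors[j]
            if ares.key == dres.key:
                continue
            if (d_is_bb and a_is_bb and dres.chain_id == ares.chain_id
                    and abs(dpos - apos) < 2):
                continue
            dist = float(np.linalg.norm(datom.coords - aatom.coords))
            if dist > d_max:
                continue
            angle = None
            if ante is not None:
                v1 = ante.coords - datom.coords
                v2 = aatom.coords - datom.coords
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if angle < ang_min:
                    continue
            bonds.append(HBond(
                (dres.chain_id, dres.number, dres.aa3, datom.name),
                (ares.chain_id, ares.number, ares.aa3, aatom.name),
                dist, angle))
    bonds.sort(key=lambda b: b.distance)
    return bonds


@dataclass
class Contact:
    residue_a: tuple[str, int, str]  # chain, number, aa3
    residue_b: tuple[str, int, str]
    min_distance: float
    atom_a: str
    atom_b: str
    kind: str  # polar | hydrophobic | mixed


def interface_contacts(structure: Structure, split: DomainSplit,
                       cutoff: float = 4.0, domain_a: str | None = None,
                       domain_b: str | None = None,
                       model: int = 0) -> list[Contact]:
    """Cross-domain residue contacts: any heavy-atom pair within ``cutoff``.

    One entry per residue pair, annotated with the closest atom pair and a
    polarity class (polar: both atoms N/O/S; hydrophobic: both C; mixed
    otherwise).
    """
    names = split.domain_names()
    if domain_a is None or domain_b is None:
        if len(names) < 2:
            raise IgtandemError("split must name two domains")
        domain_a, domain_b = names[0], names[-1]
    res_a = split.residues_of(structure, domain_a, model)
    res_b = split.residues_of(structure, domain_b, model)
    best: dict[tuple, Contact] = {}
    coords_b = []
    index_b = []
    for r in res_b:
        for a in r.atoms:
            coords_b.append(a.coords)
            index_b.append((r, a))
    tree = cKDTree(np.array(coords_b))
    polar_elements = {"N", "O", "S"}
    for r in res_a:
        for atom in r.atoms:
            for j in tree.query_ball_point(atom.coords, cutoff):
                rb, ab = index_b[j]
                d = float(np.linalg.norm(atom.coords - ab.coords))
                key = (r.key, rb.key)
                if key not in best or d < best[key].min_distance:
                    ea, eb = atom.element.capitalize(), ab.element.capitalize()
                    if ea in polar_elements and eb in polar_elements:
                        kind = "polar"
                    elif ea == "C" and eb == "C":
                        kind = "hydrophobic"
                    else:
                        kind = "mixed"
                    best[key] = Contact(
                        (r.chain_id, r.number, r.aa3),
                        (rb.chain_id, rb.number, rb.aa3),
                        d, atom.name, ab.name, kind)
    return sorted(best.values(), key=lambda c: c.min_distance)


def _sidechain_refs(residue) -> list:
    return [a for a in residue.atoms if a.name not in BACKBONE_ATOMS]


def _domain_of(split: DomainSplit, chain: str, number: int) -> str | None:
    for name, (cid, a, b) in split.ranges.items():
        if cid == chain and a <= number <= b:
            return name
    return None


def burial_fraction(structure: Structure, split: DomainSplit,
                    residue: tuple[str, int], model: int = 0,
                    probe: float = 1.4, n_points: int = 960) -> float:
    """Side-chain burial of one residue at the tandem interface.

    1 - SASA(side chain in the full tandem) / SASA(side chain in its
    isolated own domain), clipped to [0, 1]. Glycine has no side chain and
    raises (pass the Calpha as a pseudo-side-chain yourself if you want a
    Gly estimate).
    """
    chain, number = residue
    res = structure.find_residue(chain, number, model=model)
    if res is None:
        raise SelectionError(f"residue {chain}:{number} not found")
    if res.aa3 == "GLY" or not _sidechain_refs(res):
        raise IgtandemError(
            f"residue {chain}:{number} ({res.aa3}) has no side-chain atoms; "
            "use a Calpha-based fallback explicitly if needed")
    home = _domain_of(split, chain, number)
    if home is None:
        raise SelectionError(f"residue {chain}:{number} not covered by split")

    def _sc_area(atom_pool: list) -> float:
        coords = np.array([a.coords for _r, a in atom_pool])
        elements = [a.element for _r, a in atom_pool]
        areas = shrake_rupley_sasa((coords, elements), probe=probe,
                                   n_points=n_points)
        sc = [k for k, (r, a) in enumerate(atom_pool)
              if r is res and a.name not in BACKBONE_ATOMS]
        return float(areas[sc].sum())

    full_pool = [(r, a) for r in structure.all_residues(model) for a in r.atoms]
    iso_pool = [(r, a) for r in split.residues_of(structure, home, model)
                for a in r.atoms]
    iso = _sc_area(iso_pool)
    if iso <= 0:
        return 0.0
    return float(np.clip(1.0 - _sc_area(full_pool) / iso, 0.0, 1.0))


@dataclass
class InterdomainGeometry:
    torsion: float  # deg, (-180, 180]
    bend: float     # deg, [0, 180]
    rise: float     # A, centroid separation


def principal_axis(ca: np.ndarray, min_anisotropy: float = 1.2) -> np.ndarray:
    """First principal axis of a Calpha cloud, oriented N->C.

    Raises for near-spherical clouds where the axis is ill-defined."""
    ca = np.asarray(ca, float)
    centered = ca - ca.mean(axis=0)
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 0 or s[0] / s[1] < min_anisotropy:
        raise DegenerateGeometryError(
            f"domain inertia nearly spherical (axis ratio "
            f"{s[0]/max(s[1],1e-12):.2f} < {min_anisotropy})")
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis


def interdomain_geometry_ca(ca_a: np.ndarray, ca_b: np.ndarray
                            ) -> InterdomainGeometry:
    """Torsion/bend/rise from two ordered Calpha coordinate arrays."""
    ca_a, ca_b = np.asarray(ca_a, float), np.asarray(ca_b, float)
    axis_a, axis_b = principal_axis(ca_a), principal_axis(ca_b)
    cen_a, cen_b = ca_a.mean(axis=0), ca_b.mean(axis=0)
    half_a = float(np.abs((ca_a - cen_a) @ axis_a).max())
    half_b = float(np.abs((ca_b - cen_b) @ axis_b).max())
    torsion = dihedral(cen_a + half_a * axis_a, cen_a, cen_b,
                       cen_b + half_b * axis_b)
    bend = float(np.degrees(np.arccos(np.clip(axis_a @ axis_b, -1, 1))))
    rise = float(np.linalg.norm(cen_b - cen_a))
    return InterdomainGeometry(torsion, bend, rise)


def interdomain_geometry(structure: Structure, split: DomainSplit,
                         domain_a: str | None = None,
                         domain_b: str | None = None,
                         model: int = 0, min_ca: int = 20
                         ) -> InterdomainGeometry:
    """Relative torsion, bend and rise of two tandem domains (see module
    docstring for the axis convention)."""
    names = split.domain_names()
    if domain_a is None or domain_b is None:
        if len(names) < 2:
            raise IgtandemError("split must name two domains")
        domain_a, domain_b = names[0], names[-1]
    cas = []
    for name in (domain_a, domain_b):
        ca = np.array([r.atom("CA").coords
                       for r in split.residues_of(structure, name, model)
                       if r.atom("CA") is not None])
        if len(ca) < min_ca:
            raise IgtandemError(
                f"domain {name}: {len(ca)} Calpha atoms, need >= {min_ca}")
        cas.append(ca)
    return interdomain_geometry_ca(*cas)


def pole_charges(structure: Structure, split: DomainSplit, window: int = 10,
                 model: int = 0) -> dict[str, tuple[int, int]]:
    """Formal-charge sums at the axial poles of each domain.

    For every domain, residues are projected onto the domain's long axis
    (oriented N->C); the ``window`` residues at the low end form the
    N-pole cap and at the high end the C-pole cap. Charges: D/E = -1,
    K/R = +1, H = 0. Returns {domain: (N-pole charge, C-pole charge)}.
    """
    out: dict[str, tuple[int, int]] = {}
    for name in split.domain_names():
        residues = [r for r in split.residues_of(structure, name, model)
                    if r.atom("CA") is not None]
        ca = np.array([r.atom("CA").coords for r in residues])
        axis = principal_axis(ca)
        proj = (ca - ca.mean(axis=0)) @ axis
        order = np.argsort(proj)
        w = min(window, len(residues))
        n_cap = [residues[k] for k in order[:w]]
        c_cap = [residues[k] for k in order[-w:]]
        out[name] = (
            sum(FORMAL_CHARGE.get(r.aa3, 0) for r in n_cap),
            sum(FORMAL_CHARGE.get(r.aa3, 0) for r in c_cap),
        )
    return out
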