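"""Primitive geometric algorithms shared by all analysis stages.

Dihedral angles follow the IUPAC sign convention and are exchanged in
degrees throughout; torsions live in (-180, 180]. Superposition is the
classic least-squares rigid fit (reflections excluded), delegated to
scipy's Rotation.align_vectors. SASA is a Shrake-Rupley implementation on
a deterministic golden-spiral sphere lattice so results are reproducible
bit-for-bit at a fixed point count. build_chain converts backbone internal
coordinates (phi/psi/omega plus idealized bond lengths and angles) to
Cartesian coordinates NeRF-style, which is how every synthetic fixture in
the package is constructed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, DihedralUndefinedError
from .structure import Atom, AtomSet, Residue, Structure, STANDARD_AA3


def _load_yaml(name: str) -> dict:
    ref = importlib.resources.files("igtandem.data").joinpath(name)
    return yaml.safe_load(ref.read_text())


_GEOM = _load_yaml("geometry.yaml")
VDW_RADII: dict[str, float] = dict(_GEOM["vdw_radii"])
BACKBONE_GEOMETRY: dict[str, float] = dict(_GEOM["backbone"])
CHAIN_BREAK_CN: float = float(_GEOM["chain_break_cn"])


def wrap_angle(a):
    """Wrap degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    return out if out.ndim else float(out)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points, IUPAC convention.

    Raises :class:`DihedralUndefinedError` when consecutive points coincide
    or p1/p4 are collinear with the central p2-p3 axis.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < 1e-9:
        raise DihedralUndefinedError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DihedralUndefinedError("collinear points: dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    return wrap_angle(-np.degrees(np.arctan2(y, x)))


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping a mobile onto a target point set."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile, target) -> SuperpositionResult:
    """Least-squares rigid superposition (rotation + translation, no
    reflection) of ``mobile`` onto ``target``; both are (n, 3) arrays or
    AtomSets with equal atom counts >= 3."""
    mob = mobile.coords if isinstance(mobile, AtomSet) else np.asarray(mobile, float)
    tgt = target.coords if isinstance(target, AtomSet) else np.asarray(target, float)
    if mob.shape != tgt.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise DegenerateGeometryError(
            f"superposition needs matching (n,3) sets, got {mob.shape} vs {tgt.shape}")
    n = mob.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"superposition needs >=3 atoms, got {n}")
    mc, tc = mob.mean(axis=0), tgt.mean(axis=0)
    a, b = mob - mc, tgt - tc
    s = np.linalg.svd(a, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError("all-collinear point set")
    rot, rssd = Rotation.align_vectors(b, a)
    r = rot.as_matrix()
    return SuperpositionResult(r, tc - r @ mc, float(rssd) / np.sqrt(n))


def golden_spiral(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice of n points."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(atoms, probe: float = 1.4, n_points: int = 960,
                       radii: dict[str, float] | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    ``atoms`` is an AtomSet or a (coords, elements) pair. Radii come from
    the element-keyed table (configurable); unknown elements raise.
    """
    if isinstance(atoms, AtomSet):
        coords = atoms.coords
        elements = [r.atom.element for r in atoms]
    else:
        coords, elements = atoms
        coords = np.asarray(coords, float)
    table = VDW_RADII if radii is None else radii
    try:
        rad = np.array([table[e.capitalize()] for e in elements], float)
    except KeyError as exc:
        raise KeyError(f"no van der Waals radius configured for element "
                       f"{exc.args[0]!r}") from exc
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    sphere = golden_spiral(n_points)
    ext = rad + probe
    tree = cKDTree(coords)
    areas = np.zeros(n)
    max_ext = ext.max()
    for i in range(n):
        pts = coords[i] + ext[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], 2 * max_ext)
                 if j != i and np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= ext[j]
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
    return areas


# ---------------------------------------------------------------------------
# phi/psi/omega tables


def phi_psi(structure: Structure, chain: str, model: int = 0):
    """Backbone dihedral table for one chain.

    Returns a pandas DataFrame with columns (number, icode, aa3, phi, psi,
    omega); angles in degrees, NaN where undefined (chain termini, chain
    breaks with C(i-1)-N(i) > 2 A, or missing atoms). Missing values are
    explicit -- never silent zeros.
    """
    import pandas as pd

    residues = structure.residues(chain, model)
    rows = []
    for i, r in enumerate(residues):
        n, ca, c = r.atom("N"), r.atom("CA"), r.atom("C")
        prev = residues[i - 1] if i > 0 else None
        nxt = residues[i + 1] if i + 1 < len(residues) else None
        phi = psi = omega = np.nan
        prev_ok = (prev is not None and prev.atom("C") is not None
                   and n is not None
                   and np.linalg.norm(prev.atom("C").coords - n.coords)
                   <= CHAIN_BREAK_CN)
        next_ok = (nxt is not None and nxt.atom("N") is not None
                   and c is not None
                   and np.linalg.norm(c.coords - nxt.atom("N").coords)
                   <= CHAIN_BREAK_CN)
        try:
            if prev_ok and all(x is not None for x in (n, ca, c)):
                phi = dihedral(prev.atom("C").coords, n.coords, ca.coords,
                               c.coords)
            if next_ok and all(x is not None for x in (n, ca, c)):
                psi = dihedral(n.coords, ca.coords, c.coords,
                               nxt.atom("N").coords)
            if (prev_ok and prev.atom("CA") is not None and ca is not None):
                omega = dihedral(prev.atom("CA").coords, prev.atom("C").coords,
                                 n.coords, ca.coords)
        except DihedralUndefinedError:
            pass
        rows.append({"number": r.number, "icode": r.insertion_code,
                     "aa3": r.aa3, "phi": phi, "psi": psi, "omega": omega})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NeRF chain building


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
           angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(ang),
                   bond * np.sin(ang) * np.cos(tor),
                   bond * np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_chain(residue_spec, chain_id: str = "A", include_cb: bool = True,
                start_number: int = 1,
                geometry: dict[str, float] | None = None) -> Structure:
    """Build a poly-backbone chain from (aa3, phi, psi, omega) tuples.

    NeRF internal-to-Cartesian construction with idealized bond geometry;
    the first residue is placed canonically (its phi is unused, as is
    omega). O atoms are placed anti to the next amide; a Cbeta is added for
    non-Gly residues when ``include_cb``. Round trip:
    ``phi_psi(build_chain(spec))`` reproduces the spec to well under 0.5
    degrees.
    """
    if not residue_spec:
        raise ValueError("empty residue spec")
    g = BACKBONE_GEOMETRY if geometry is None else geometry
    for aa3, *_ in residue_spec:
        if aa3 not in STANDARD_AA3:
            raise ValueError(f"unknown residue code {aa3!r}")

    residues: list[Residue] = []
    prev_n = prev_ca = prev_c = None
    for i, spec in enumerate(residue_spec):
        aa3, phi, psi = spec[0], float(spec[1]), float(spec[2])
        omega = float(spec[3]) if len(spec) > 3 else 180.0
        if i == 0:
            n = np.zeros(3)
            ca = np.array([g["bond_n_ca"], 0.0, 0.0])
            ang = np.radians(g["angle_n_ca_c"])
            c = ca + g["bond_ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            prev_psi = float(residue_spec[i - 1][2])
            n = _place(prev_n, prev_ca, prev_c, g["bond_c_n"],
                       g["angle_ca_c_n"], prev_psi)
            ca = _place(prev_ca, prev_c, n, g["bond_n_ca"],
                        g["angle_c_n_ca"], omega)
            c = _place(prev_c, n, ca, g["bond_ca_c"],
                       g["angle_n_ca_c"], phi)
        o = _place(n, ca, c, g["bond_c_o"], g["angle_ca_c_o"],
                   wrap_angle(psi + 180.0))
        atoms = [Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c),
                 Atom("O", "O", o)]
        if include_cb and aa3 != "GLY":
            cb = _place(n, c, ca, g["bond_ca_cb"], g["angle_n_ca_cb"],
                        g["improper_n_c_ca_cb"])
            atoms.append(Atom("CB", "C", cb))
        residues.append(Residue(chain_id, start_number + i, "", aa3, atoms))
        prev_n, prev_ca, prev_c = n, ca, c
    return Structure([{chain_id: residues}])


def transform_structure(structure: Structure, rotation: np.ndarray,
                        translation: np.ndarray, model: int = 0) -> Structure:
    """Return a copy with ``x -> R x + t`` applied to every atom."""
    import copy

    out = copy.deepcopy(structure)
    for r in out.all_residues(model):
        for a in r.atoms:
            a.coords = rotation @ a.coords + np.asarray(translation, float)
    return out
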