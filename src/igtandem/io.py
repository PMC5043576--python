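"""Structure and trajectory file I/O.

PDB reading/writing is delegated to gemmi; this module converts between
gemmi's hierarchy and the package's light containers, applying the altloc
and hydrogen policies at conversion time. The plain-text XYZ frame format
(count header, then ``element x y z`` lines) and the trajectory manifest
(TSV: path, group label) are parsed directly.
"""

from __future__ import annotations

import os

import gemmi
import numpy as np

from .errors import ParseError
from .structure import Atom, Model, Residue, Structure, TrajectoryEnsemble


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    """Keep the highest-occupancy conformer; ties resolve to altloc 'A'
    (blank sorts first, i.e. a lone unlabelled atom always wins)."""
    return min(atoms, key=lambda a: (-a.occ, a.altloc or ""))


def _convert(st: gemmi.Structure, keep_waters: bool,
             keep_hydrogens: bool) -> Structure:
    models: list[Model] = []
    for gm in st:
        model: Model = {}
        for gch in gm:
            residues: list[Residue] = []
            for gr in gch:
                if not keep_waters and gr.name in ("HOH", "WAT", "DOD"):
                    continue
                by_name: dict[str, list[gemmi.Atom]] = {}
                for ga in gr:
                    el = ga.element.name
                    if not keep_hydrogens and el in ("H", "D"):
                        continue
                    by_name.setdefault(ga.name, []).append(ga)
                atoms = []
                for name, gatoms in by_name.items():
                    ga = _pick_altloc(gatoms)
                    atoms.append(Atom(
                        name=name,
                        element=ga.element.name or "X",
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        altloc=ga.altloc or "",
                    ))
                if atoms:
                    residues.append(Residue(
                        chain_id=gch.name,
                        number=gr.seqid.num,
                        insertion_code=(gr.seqid.icode or "").strip(),
                        aa3=gr.name,
                        atoms=atoms,
                    ))
            if residues:
                model[gch.name] = residues
        if model:
            models.append(model)
    if not models:
        raise ParseError(f"{st.name or 'structure'}: no atoms found")
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return Structure(models, id=st.name, resolution=resolution)


def read_structure(path: str | os.PathLike, format: str = "pdb",
                   keep_waters: bool = True,
                   keep_hydrogens: bool = False) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Altloc policy: for each atom name within a residue the highest-occupancy
    conformer is retained (ties -> 'A'). Hydrogens are dropped by default.
    """
    if format != "pdb":
        raise ParseError(f"unsupported structure format {format!r}")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_pdb(path)
    except (RuntimeError, ValueError) as exc:
        # gemmi reports the offending line in its message
        raise ParseError(f"{path}: {exc}") from exc
    st.name = st.name or os.path.basename(path)
    return _convert(st, keep_waters, keep_hydrogens)


def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.id or "igtandem"
    for model in structure.models:
        gm = gemmi.Model(len(st) + 1)
        for cid, residues in model.items():
            gch = gemmi.Chain(cid)
            for r in residues:
                gr = gemmi.Residue()
                gr.name = r.aa3
                gr.seqid = gemmi.SeqId(r.number, r.insertion_code or " ")
                for a in r.atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*a.coords)
                    ga.occ = a.occupancy
                    ga.altloc = a.altloc or "\0"
                    gr.add_atom(ga)
                gch.add_residue(gr)
            gm.add_chain(gch)
        st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write a Structure as PDB (coordinates at the format's 3-decimal
    precision, author numbering preserved exactly)."""
    _to_gemmi(structure).write_pdb(os.fspath(path))


def ensemble_from_structure(structure: Structure, group: str = "",
                            source: str = "") -> TrajectoryEnsemble:
    """Stack the models of a (multi-model) Structure into an ensemble."""
    labels = [(r.chain_id, r.number, r.insertion_code, r.aa3, a.name)
              for r in structure.all_residues(0) for a in r.atoms]
    frames = []
    for i, _model in enumerate(structure.models):
        coords = [a.coords for r in structure.all_residues(i) for a in r.atoms]
        if len(coords) != len(labels):
            raise ParseError(
                f"frame {i}: {len(coords)} atoms, expected {len(labels)}")
        frames.append(np.array(coords))
    src = source or structure.id
    n = len(frames)
    return TrajectoryEnsemble(np.stack(frames), labels, [group] * n,
                              [f"{src}[{i}]" for i in range(n)])


def _read_xyz_frames(path: str) -> tuple[np.ndarray, list[str]]:
    """Parse the plain-text frame format: per frame a line with the atom
    count, an optional comment line, then ``element x y z`` lines."""
    frames: list[np.ndarray] = []
    elements: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    frame_no = 0
    n_expected: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise ParseError(
                f"{path}: line {i+1}: expected atom count, got {lines[i]!r}"
            ) from exc
        i += 1
        # tolerate a standard-XYZ comment line
        if i < len(lines):
            parts = lines[i].split()
            if not (len(parts) >= 4 and _is_float(parts[1])):
                i += 1
        rows = []
        els = []
        for k in range(n):
            if i >= len(lines):
                raise ParseError(f"{path}: frame {frame_no}: truncated "
                                 f"(expected {n} atoms, got {k})")
            parts = lines[i].split()
            if len(parts) < 4 or not all(_is_float(p) for p in parts[1:4]):
                raise ParseError(f"{path}: line {i+1}: expected "
                                 f"'element x y z', got {lines[i]!r}")
            els.append(parts[0])
            rows.append([float(p) for p in parts[1:4]])
            i += 1
        if n_expected is None:
            n_expected, elements = n, els
        elif n != n_expected:
            raise ParseError(f"{path}: frame {frame_no} has {n} atoms, "
                             f"expected {n_expected}")
        frames.append(np.array(rows))
        frame_no += 1
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return np.stack(frames), elements


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_ensemble(path: str | os.PathLike, format: str | None = None,
                  group: str = "") -> TrajectoryEnsemble:
    """Read one trajectory file (multi-model PDB or XYZ frames).

    All frames must share atom count and ordering; a mismatching frame is
    reported by index.
    """
    path = os.fspath(path)
    if format is None:
        format = "xyz" if path.endswith((".xyz", ".txt")) else "pdb"
    if format == "pdb":
        st = read_structure(path)
        _check_topology(st, path)
        return ensemble_from_structure(st, group=group, source=path)
    if format == "xyz":
        coords, elements = _read_xyz_frames(path)
        labels = [("", i + 1, "", "UNK", el.upper())
                  for i, el in enumerate(elements)]
        n = coords.shape[0]
        return TrajectoryEnsemble(coords, labels, [group] * n,
                                  [f"{path}[{i}]" for i in range(n)])
    raise ParseError(f"unsupported trajectory format {format!r}")


def _check_topology(st: Structure, path: str) -> None:
    ref = [(r.chain_id, r.number, r.insertion_code, len(r.atoms))
           for r in st.all_residues(0)]
    for i in range(1, len(st.models)):
        cur = [(r.chain_id, r.number, r.insertion_code, len(r.atoms))
               for r in st.all_residues(i)]
        if cur != ref:
            raise ParseError(f"{path}: frame {i} topology differs from frame 0")


def read_manifest(path: str | os.PathLike) -> TrajectoryEnsemble:
    """Read a manifest (TSV: one ``path<TAB>group`` line per trajectory file,
    paths relative to the manifest) and concatenate all frames."""
    path = os.fspath(path)
    base = os.path.dirname(os.path.abspath(path))
    parts: list[TrajectoryEnsemble] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}: line {ln}: expected 'path group', "
                                 f"got {line!r}")
            fpath, grp = fields
            if not os.path.isabs(fpath):
                fpath = os.path.join(base, fpath)
            parts.append(read_ensemble(fpath, group=grp))
    if not parts:
        raise ParseError(f"{path}: empty manifest")
    return TrajectoryEnsemble.concatenate(parts)
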