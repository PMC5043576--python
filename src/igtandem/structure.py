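"""In-memory model of protein structures and trajectory ensembles.

The hierarchy is deliberately light: a :class:`Structure` holds one or more
models, each model an ordered mapping ``chain id -> list of Residue``.
Coordinates are in Angstrom with author residue numbering kept verbatim
(an optional offset map aligns construct numbering to full-length titin
numbering, e.g. T2850). Hydrogens are ignored throughout the package: every
geometric quantity is computed on heavy atoms only, matching what deposited
X-ray structures provide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    """One heavy atom: PDB atom label, element symbol and Cartesian coords (A)."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str
    aa3: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_standard(self) -> bool:
        return self.aa3 in STANDARD_AA3

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)


# A model is an ordered mapping chain id -> residues in file order.
Model = dict[str, list["Residue"]]


@dataclass
class Structure:
    models: list[Model]
    id: str = ""
    resolution: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("structure must contain at least one model")
        for model in self.models:
            seen: set[tuple[str, int, str]] = set()
            for residues in model.values():
                for r in residues:
                    if r.key in seen:
                        raise ValueError(f"duplicate residue {r.key} in model")
                    seen.add(r.key)

    @property
    def first_model(self) -> Model:
        return self.models[0]

    def chains(self, model: int = 0) -> list[str]:
        return list(self.models[model].keys())

    def residues(self, chain: str, model: int = 0) -> list[Residue]:
        try:
            return self.models[model][chain]
        except KeyError as exc:
            raise SelectionError(f"chain {chain!r} not in structure") from exc

    def all_residues(self, model: int = 0) -> list[Residue]:
        out: list[Residue] = []
        for residues in self.models[model].values():
            out.extend(residues)
        return out

    def find_residue(self, chain: str, number: int, icode: str = "",
                     model: int = 0) -> Residue | None:
        for r in self.residues(chain, model):
            if r.number == number and r.insertion_code == icode:
                return r
        return None

    def renumber(self, offset_map: dict[str, int]) -> "Structure":
        """Return a copy with per-chain numbering offsets applied.

        The offset aligning deposited construct numbering to full-length
        titin numbering is not derivable from the coordinates themselves,
        so it must be supplied explicitly.
        """
        models = []
        for model in self.models:
            new: Model = {}
            for cid, residues in model.items():
                off = offset_map.get(cid, 0)
                new[cid] = [
                    Residue(r.chain_id, r.number + off, r.insertion_code, r.aa3,
                            [Atom(a.name, a.element, a.coords.copy(), a.occupancy,
                                  a.altloc) for a in r.atoms])
                    for r in residues
                ]
            models.append(new)
        return Structure(models, self.id, self.resolution, dict(self.metadata))


@dataclass(frozen=True)
class AtomRef:
    """One atom in the context of its residue, as stored by an AtomSet."""

    chain_id: str
    res_number: int
    insertion_code: str
    aa3: str
    atom: Atom


class AtomSet:
    """Ordered, immutable selection of atoms.

    Ordering is stable: (chain id, residue number, insertion code, atom name).
    """

    def __init__(self, refs: list[AtomRef]):
        self._refs = sorted(
            refs, key=lambda r: (r.chain_id, r.res_number, r.insertion_code,
                                 r.atom.name))

    def __len__(self) -> int:
        return len(self._refs)

    def __iter__(self):
        return iter(self._refs)

    def __getitem__(self, i):
        return self._refs[i]

    @property
    def coords(self) -> np.ndarray:
        if not self._refs:
            return np.zeros((0, 3))
        return np.array([r.atom.coords for r in self._refs])

    @property
    def labels(self) -> list[tuple[str, int, str, str, str]]:
        return [(r.chain_id, r.res_number, r.insertion_code, r.aa3, r.atom.name)
                for r in self._refs]


_RESI_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def select(structure: Structure, query: str, model: int = 0) -> AtomSet:
    """Select atoms with a small keyword query language.

    Clauses are whitespace separated and combined with AND; filler words
    ("of", "and", "the") are ignored. Supported clauses::

        backbone | sidechain          atom kind
        chain <id>                    chain filter
        resi <a>[-<b>]                author residue number / range
        residue type <AA3> | resn <AA3>
        element <sym>                 element filter
        name <atom name>              explicit atom-name filter
        <ATOMNAME>                    bare token of 2-4 chars, e.g. CA, OG1
        <X>                           bare single char = element, e.g. O

    An empty selection is a valid (empty) result, never an error.
    """
    tokens = query.split()
    kind: str | None = None
    chain: str | None = None
    resn: str | None = None
    resi: tuple[int, int] | None = None
    element: str | None = None
    names: set[str] = set()

    i = 0
    while i < len(tokens):
        tok = tokens[i]
        low = tok.lower()
        if low in ("of", "and", "the", "atoms", "atom"):
            i += 1
        elif low in ("backbone", "sidechain"):
            kind = low
            i += 1
        elif low == "chain":
            if i + 1 >= len(tokens):
                raise SelectionError("'chain' requires an id")
            chain = tokens[i + 1]
            i += 2
        elif low in ("resn", "resname"):
            if i + 1 >= len(tokens):
                raise SelectionError(f"{tok!r} requires a residue name")
            resn = tokens[i + 1].upper()
            i += 2
        elif low == "residue" and i + 2 < len(tokens) and tokens[i + 1].lower() == "type":
            resn = tokens[i + 2].upper()
            i += 3
        elif low == "resi":
            if i + 1 >= len(tokens):
                raise SelectionError("'resi' requires a number or range")
            m = _RESI_RE.match(tokens[i + 1])
            if not m:
                raise SelectionError(f"bad residue range {tokens[i+1]!r}")
            a = int(m.group(1))
            b = int(m.group(2)) if m.group(2) else a
            resi = (min(a, b), max(a, b))
            i += 2
        elif low == "element":
            if i + 1 >= len(tokens):
                raise SelectionError("'element' requires a symbol")
            element = tokens[i + 1].capitalize()
            i += 2
        elif low == "name":
            if i + 1 >= len(tokens):
                raise SelectionError("'name' requires an atom name")
            names.add(tokens[i + 1].upper())
            i += 2
        elif tok.isalnum() and 2 <= len(tok) <= 4 and tok.upper() == tok:
            names.add(tok)
            i += 1
        elif len(tok) == 1 and tok.isalpha():
            element = tok.capitalize()
            i += 1
        else:
            raise SelectionError(f"cannot parse selection token {tok!r}")

    refs: list[AtomRef] = []
    for cid, residues in structure.models[model].items():
        if chain is not None and cid != chain:
            continue
        for r in residues:
            if resn is not None and r.aa3 != resn:
                continue
            if resi is not None and not (resi[0] <= r.number <= resi[1]):
                continue
            for a in r.atoms:
                if kind == "backbone" and a.name not in BACKBONE_ATOMS:
                    continue
                if kind == "sidechain" and a.name in BACKBONE_ATOMS:
                    continue
                if element is not None and a.element.capitalize() != element:
                    continue
                if names and a.name not in names:
                    continue
                refs.append(AtomRef(cid, r.number, r.insertion_code, r.aa3, a))
    return AtomSet(refs)


@dataclass
class DomainSplit:
    """Named, ordered, non-overlapping residue ranges (author numbering).

    ``ranges`` maps a domain name (e.g. "I10") to (chain, first, last),
    inclusive on both ends. Linker segments are ordinary named ranges;
    by convention names starting with "linker" are skipped when a pair of
    domains is required.
    """

    ranges: dict[str, tuple[str, int, int]]

    def __post_init__(self) -> None:
        per_chain: dict[str, list[tuple[int, int, str]]] = {}
        for name, (chain, a, b) in self.ranges.items():
            if a > b:
                raise ValueError(f"range {name}: start {a} > end {b}")
            per_chain.setdefault(chain, []).append((a, b, name))
        for chain, spans in per_chain.items():
            spans.sort()
            for (a1, b1, n1), (a2, b2, n2) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise ValueError(
                        f"ranges {n1} and {n2} overlap on chain {chain}")

    @classmethod
    def parse(cls, text: str, default_chain: str = "A") -> "DomainSplit":
        """Parse e.g. ``"I10:A:2835-2895,I11:2896-2960"``; chain optional."""
        ranges: dict[str, tuple[str, int, int]] = {}
        for part in text.split(","):
            bits = part.strip().split(":")
            if len(bits) == 2:
                name, span = bits
                chain = default_chain
            elif len(bits) == 3:
                name, chain, span = bits
            else:
                raise ValueError(f"cannot parse split component {part!r}")
            m = _RESI_RE.match(span)
            if not m or m.group(2) is None:
                raise ValueError(f"bad residue span {span!r} in {part!r}")
            ranges[name] = (chain, int(m.group(1)), int(m.group(2)))
        return cls(ranges)

    def domain_names(self, skip_linkers: bool = True) -> list[str]:
        names = list(self.ranges)
        if skip_linkers:
            names = [n for n in names if not n.lower().startswith("link")]
        return names

    def residues_of(self, structure: Structure, name: str,
                    model: int = 0) -> list[Residue]:
        chain, a, b = self.ranges[name]
        out = [r for r in structure.residues(chain, model) if a <= r.number <= b]
        if not out:
            raise SelectionError(
                f"split range {name} ({chain}:{a}-{b}) matches no residues")
        return out

    def atoms_of(self, structure: Structure, name: str, kind: str | None = None,
                 atom_names: tuple[str, ...] | None = None,
                 model: int = 0) -> AtomSet:
        refs: list[AtomRef] = []
        for r in self.residues_of(structure, name, model):
            for a in r.atoms:
                if kind == "backbone" and a.name not in BACKBONE_ATOMS:
                    continue
                if kind == "sidechain" and a.name in BACKBONE_ATOMS:
                    continue
                if atom_names is not None and a.name not in atom_names:
                    continue
                refs.append(AtomRef(r.chain_id, r.number, r.insertion_code,
                                    r.aa3, a))
        return AtomSet(refs)


@dataclass
class TrajectoryEnsemble:
    """Frames x atoms x 3 coordinate stack with per-frame group labels.

    ``atom_labels`` carries (chain, residue number, insertion code, residue
    name, atom name) per atom so selections and domain splits can be applied
    to frames exactly as to structures. Frames stand in for simulation
    snapshots; groups tag their provenance (e.g. "wt" vs "mut").
    """

    coords: np.ndarray
    atom_labels: list[tuple[str, int, str, str, str]]
    groups: list[str]
    sources: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        f, n, _ = self.coords.shape
        if len(self.atom_labels) != n:
            raise ValueError("atom_labels length must match atom count")
        if len(self.groups) != f or len(self.sources) != f:
            raise ValueError("groups/sources must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select_indices(self, atom_names: tuple[str, ...] | None = None,
                       kind: str | None = None, chain: str | None = None,
                       residues: tuple[int, int] | None = None) -> np.ndarray:
        idx = []
        for i, (cid, num, _ic, _aa, name) in enumerate(self.atom_labels):
            if atom_names is not None and name not in atom_names:
                continue
            if kind == "backbone" and name not in BACKBONE_ATOMS:
                continue
            if kind == "sidechain" and name in BACKBONE_ATOMS:
                continue
            if chain is not None and cid != chain:
                continue
            if residues is not None and not (residues[0] <= num <= residues[1]):
                continue
            idx.append(i)
        return np.array(idx, dtype=int)

    def domain_indices(self, split: DomainSplit, name: str,
                       atom_names: tuple[str, ...] | None = None,
                       kind: str | None = None) -> np.ndarray:
        chain, a, b = split.ranges[name]
        return self.select_indices(atom_names=atom_names, kind=kind,
                                   chain=chain, residues=(a, b))

    @classmethod
    def concatenate(cls, parts: list["TrajectoryEnsemble"]) -> "TrajectoryEnsemble":
        if not parts:
            raise ValueError("nothing to concatenate")
        first = parts[0]
        for p in parts[1:]:
            if p.n_atoms != first.n_atoms:
                raise ValueError("atom counts differ between ensembles")
        return cls(
            np.concatenate([p.coords for p in parts], axis=0),
            first.atom_labels,
            sum((p.groups for p in parts), []),
            sum((p.sources for p in parts), []),
        )
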