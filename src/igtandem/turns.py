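"""Beta-turn detection, typing, Ramachandran region labels and the
position-specific residue-propensity survey.

A beta-turn is a four-residue chain reversal (i..i+3) with Calpha(i) to
Calpha(i+3) within a cutoff (default 7 A) whose central residues are not
part of a continuous helix. Types follow the Hutchinson-Thornton convention:
the (phi, psi) of i+1 and i+2 must fall within +/-30 degrees of a type's
canonical values, with one of the four angles allowed to stray to +/-45
degrees; anything else is type IV (unclassified). Type II places i+2 in the
left-handed helical (alphaL) region -- positive phi, sterically strained for
any residue carrying a side chain, which is why surveys of type-II turns
find glycine dominating that position and branched-Cbeta residues (Ile, Val)
or Pro nearly absent. Threonine is the interesting exception: its Cbeta is
branched, but its hydroxyl can hydrogen-bond back to the preceding carbonyl
(checked here by :func:`thr_i2_hbond_check`), turning the clash into a
stabilizing contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IgtandemError
from .geometry import _load_yaml, phi_psi, CHAIN_BREAK_CN
from .structure import AA3_TO_1, Structure

TURN_TYPES = ("I", "I'", "II", "II'", "VIII")

#: canonical (phi_{i+1}, psi_{i+1}, phi_{i+2}, psi_{i+2}) in degrees
CANONICAL_TURN_DIHEDRALS: dict[str, tuple[float, float, float, float]] = {
    "I": (-60.0, -30.0, -90.0, 0.0),
    "I'": (60.0, 30.0, 90.0, 0.0),
    "II": (-60.0, 120.0, 80.0, 0.0),
    "II'": (60.0, -120.0, -80.0, 0.0),
    "VIII": (-60.0, -30.0, -120.0, 120.0),
}

UNCLASSIFIED = "IV"

_RAMA = _load_yaml("rama_regions.yaml")

RAMA_LABELS = ("core alphaR", "core beta", "core alphaL", "allowed",
               "generously allowed", "disallowed")


@dataclass(frozen=True)
class RegionLabel:
    """Ramachandran tier label plus the specific alphaL flag."""

    label: str
    alphaL: bool


def _ang_dev(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def classify_turn_type(phi1: float, psi1: float, phi2: float, psi2: float,
                       window: float = 30.0, slack: float = 45.0) -> str:
    """Assign the nearest canonical turn type, or "IV" if none fits.

    A type matches when all four dihedral deviations from canon are within
    ``window`` except that a single angle may deviate up to ``slack``. If
    several types match, the one with the smallest total deviation wins.
    """
    for v in (phi1, psi1, phi2, psi2):
        if v is None or not np.isfinite(v):
            raise IgtandemError("classify_turn_type: missing dihedral angle")
    best = None
    for ttype, canon in CANONICAL_TURN_DIHEDRALS.items():
        devs = sorted(
            _ang_dev(a, c) for a, c in zip((phi1, psi1, phi2, psi2), canon))
        if devs[2] <= window and devs[3] <= slack:
            total = sum(devs)
            if best is None or total < best[0]:
                best = (total, ttype)
    return best[1] if best else UNCLASSIFIED


def rama_region(phi: float, psi: float,
                regions: list[dict] | None = None) -> RegionLabel:
    """Four-tier Ramachandran label plus the alphaL flag.

    Regions are configurable box lists (first match wins; fallback is
    "disallowed"). The alphaL flag is independent of the tier: it marks the
    positive-phi left-handed helical window.
    """
    if not (np.isfinite(phi) and np.isfinite(psi)):
        raise IgtandemError("rama_region: undefined phi/psi")
    spec = _RAMA["regions"] if regions is None else regions
    label = "disallowed"
    for region in spec:
        if any(b[0] <= phi <= b[1] and b[2] <= psi <= b[3]
               for b in region["boxes"]):
            label = region["label"]
            break
    fp, fs = _RAMA["alphaL_flag"]["phi"], _RAMA["alphaL_flag"]["psi"]
    flag = (fp[0] < phi < fp[1]) and (fs[0] < psi < fs[1])
    return RegionLabel(label, flag)


@dataclass
class TurnAnnotation:
    chain: str
    residues: list[tuple[int, str]]  # four (number, aa3) for i..i+3
    type: str
    dihedrals: tuple[float, float, float, float]  # phi1, psi1, phi2, psi2
    ca_distance: float

    @property
    def sequence(self) -> str:
        return "".join(AA3_TO_1.get(aa3, "X") for _n, aa3 in self.residues)


def _helical_runs(table: pd.DataFrame, tol: float = 30.0,
                  min_run: int = 4) -> np.ndarray:
    """Boolean mask of residues inside an alpha-helical run: (phi, psi)
    within ``tol`` of (-57, -47) for >= ``min_run`` consecutive residues."""
    near = np.array([
        np.isfinite(row.phi) and np.isfinite(row.psi)
        and _ang_dev(row.phi, -57.0) <= tol and _ang_dev(row.psi, -47.0) <= tol
        for row in table.itertuples()
    ])
    mask = np.zeros(len(near), dtype=bool)
    i = 0
    while i < len(near):
        if near[i]:
            j = i
            while j < len(near) and near[j]:
                j += 1
            if j - i >= min_run:
                mask[i:j] = True
            i = j
        else:
            i += 1
    return mask


def detect_turns(structure: Structure, ca_cutoff: float = 7.0,
                 exclude_helix: bool = True, model: int = 0
                 ) -> list[TurnAnnotation]:
    """Find all four-residue beta-turn windows in every chain.

    A window qualifies when its four residues are consecutive (no chain
    break on any peptide bond), Calpha(i)-Calpha(i+3) <= ``ca_cutoff``, and
    (optionally) i+1 and i+2 are not both inside a continuous helix.
    """
    out: list[TurnAnnotation] = []
    for chain in structure.chains(model):
        residues = structure.residues(chain, model)
        if len(residues) < 4:
            continue
        table = phi_psi(structure, chain, model)
        helix = (_helical_runs(table) if exclude_helix
                 else np.zeros(len(residues), bool))
        for i in range(len(residues) - 3):
            window = residues[i:i + 4]
            cas = [r.atom("CA") for r in window]
            if any(ca is None for ca in cas):
                continue
            if _has_break(window):
                continue
            d = float(np.linalg.norm(cas[0].coords - cas[3].coords))
            if d > ca_cutoff:
                continue
            if exclude_helix and helix[i + 1] and helix[i + 2]:
                continue
            row1, row2 = table.iloc[i + 1], table.iloc[i + 2]
            angles = (row1.phi, row1.psi, row2.phi, row2.psi)
            if not all(np.isfinite(a) for a in angles):
                continue
            ttype = classify_turn_type(*angles)
            out.append(TurnAnnotation(
                chain=chain,
                residues=[(r.number, r.aa3) for r in window],
                type=ttype,
                dihedrals=tuple(float(a) for a in angles),
                ca_distance=d,
            ))
    return out


def _has_break(window) -> bool:
    for a, b in zip(window, window[1:]):
        c, n = a.atom("C"), b.atom("N")
        if c is None or n is None:
            return True
        if np.linalg.norm(c.coords - n.coords) > CHAIN_BREAK_CN:
            return True
    return False


POSITIONS = ("i", "i+1", "i+2", "i+3")


@dataclass
class PropensityTable:
    """Per-position amino-acid counts over a set of turns."""

    counts: pd.DataFrame  # index: 20 aa3 codes, columns: POSITIONS
    total: int
    skipped_nonstandard: int = 0
    _freq: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def freq(self) -> pd.DataFrame:
        col_sums = self.counts.sum(axis=0)
        return self.counts / col_sums.replace(0, np.nan)

    def to_tsv(self, path) -> None:
        rows = []
        freq = self.freq
        for pos in POSITIONS:
            for aa3 in self.counts.index:
                rows.append({"position": pos, "aa": aa3,
                             "count": int(self.counts.loc[aa3, pos]),
                             "freq": freq.loc[aa3, pos]})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def propensity_survey(structures, turn_type: str | None = "II",
                      dedup: str = "sequence", ca_cutoff: float = 7.0
                      ) -> PropensityTable:
    """Residue-identity counts at each turn position across structures.

    ``dedup`` controls what counts as a unique turn: "sequence" keeps one
    instance per (4-residue sequence, type) key across the whole input
    (matching the idea of a survey of unique turns), "none" counts every
    occurrence. Frequencies normalize per position.
    """
    if dedup not in ("sequence", "none"):
        raise ValueError(f"unknown dedup policy {dedup!r}")
    aa_index = sorted(AA3_TO_1)
    counts = pd.DataFrame(0, index=aa_index, columns=list(POSITIONS))
    seen: set[tuple[str, str]] = set()
    total = 0
    skipped = 0
    for structure in structures:
        for turn in detect_turns(structure, ca_cutoff=ca_cutoff):
            if turn_type is not None and turn.type != turn_type:
                continue
            if dedup == "sequence":
                key = (turn.sequence, turn.type)
                if key in seen:
                    continue
                seen.add(key)
            if any(aa3 not in AA3_TO_1 for _n, aa3 in turn.residues):
                skipped += 1
                continue
            for pos, (_n, aa3) in zip(POSITIONS, turn.residues):
                counts.loc[aa3, pos] += 1
            total += 1
    return PropensityTable(counts, total, skipped)


@dataclass
class HBondReport:
    present: bool
    distance: float


def thr_i2_hbond_check(structure: Structure, turn: TurnAnnotation,
                       d_max: float = 3.5, ang_min: float = 120.0,
                       model: int = 0) -> HBondReport:
    """Check the Thr-specific stabilizing hydrogen bond at turn position
    i+2: side-chain OG1 of residue i+2 to the main-chain carbonyl O of
    residue i+1, using the package-wide geometric criterion (distance plus
    antecedent angle where the CB antecedent is present)."""
    num2, aa2 = turn.residues[2]
    if aa2 != "THR":
        raise IgtandemError(
            f"residue i+2 is {aa2}, not THR: hydroxyl check does not apply")
    r2 = structure.find_residue(turn.chain, num2, model=model)
    r1 = structure.find_residue(turn.chain, turn.residues[1][0], model=model)
    og1 = r2.atom("OG1") if r2 else None
    o = r1.atom("O") if r1 else None
    if og1 is None or o is None:
        raise IgtandemError("missing OG1 or carbonyl O atom for H-bond check")
    dist = float(np.linalg.norm(og1.coords - o.coords))
    present = dist <= d_max
    cb = r2.atom("CB")
    if present and cb is not None:
        v1 = cb.coords - og1.coords
        v2 = o.coords - og1.coords
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        present = bool(np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                       >= ang_min)
    return HBondReport(bool(present), dist)
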