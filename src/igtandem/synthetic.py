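"""Synthetic-data generators with known ground truth.

Every input class the analysis stages consume can be generated here at
desk scale: an idealized two-domain Ig-like tandem with planted
twist/bend geometry, rigid-body hinge trajectories with Gaussian thermal
noise, beta-turn libraries with planted per-position residue
compositions, HSQC peak-list pairs with planted chemical-shift
perturbations, and two-state melt curves. Generators are pure functions
of (parameters, seed): the root seed is expanded into independent named
substreams so adding a generator never perturbs another's draws, and
every generator records its ground truth (in object metadata and,
optionally, a JSON sidecar) for recovery checks.

The generated data emulate the *structure* of the real inputs, not their
physics: domains are idealized beta-meanders, hinge motion is strictly
rigid-body, peak positions are uniform random, noise is Gaussian and
uncorrelated. Recovery tests on these data validate the analysis
machinery, not force-field realism.
"""

from __future__ import annotations

import json
import zlib

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import IgtandemError
from .geometry import build_chain
from .melting import MeltingCurve, boltzmann
from .nmr import PeakList
from .structure import (AA3_TO_1, DomainSplit, Residue, Structure,
                        TrajectoryEnsemble)
from .turns import CANONICAL_TURN_DIHEDRALS

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
ALL_AA3 = sorted(AA3_TO_1)


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent deterministic substream named by ``stream``."""
    tag = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((int(seed), tag)))


def write_sidecar(truth: dict, path) -> None:
    """Write a ground-truth sidecar as JSON (numpy types converted)."""

    def conv(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=conv)


# ---------------------------------------------------------------------------
# Ig-tandem structure


def _meander_spec(n_res: int, rng: np.random.Generator, jitter: float,
                  charged_poles: bool):
    """Residue spec for one idealized 3-strand beta-meander domain."""
    m = (n_res - 4) // 3
    lengths = [m, m, n_res - 4 - 2 * m]
    strand = (-120.0, 130.0)
    # a II'-type connecting turn reverses the chain into a slim,
    # near-planar antiparallel meander (long axis >> width >> thickness),
    # which keeps the domain's principal axis sharply defined
    turn = [(60.0, -120.0), (-80.0, 0.0)]
    dihedrals: list[tuple[float, float]] = []
    for si, ln in enumerate(lengths):
        dihedrals.extend([strand] * ln)
        if si < 2:
            dihedrals.extend(turn)
    names = ["ALA"] * n_res
    if charged_poles:
        for i in range(3):
            names[i] = "LYS"
            names[-1 - i] = "GLU"
    spec = []
    for name, (phi, psi) in zip(names, dihedrals):
        spec.append((name, phi + rng.uniform(-jitter, jitter),
                     psi + rng.uniform(-jitter, jitter), 180.0))
    return spec


def _axis_to_z(ca: np.ndarray) -> np.ndarray:
    """Rotation matrix taking the N->C principal axis of ``ca`` to +z."""
    centered = ca - ca.mean(axis=0)
    _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    rot, _ = Rotation.align_vectors(np.array([[0.0, 0.0, 1.0]]),
                                    axis[None, :])
    return rot.as_matrix()


def _structure_coords(st: Structure) -> np.ndarray:
    return np.array([a.coords for r in st.all_residues(0) for a in r.atoms])


def gen_ig_tandem(n_res_per_domain: int = 90, linker: str = "TL",
                  twist: float = 0.0, bend: float = 0.0, seed: int = 0,
                  tilt: float = 1.5, gap: float = 3.5,
                  dihedral_jitter: float = 2.0,
                  charged_poles: bool = True) -> Structure:
    """Two idealized Ig-like domains joined by a 2-residue linker, the
    second placed at a planted twist/bend relative to the first.

    Each domain is a 3-strand beta-meander whose long axis is tilted
    ``tilt`` degrees off the tandem (z) axis; the tilt keeps the
    tip-dihedral torsion convention well-conditioned in the extended
    arrangement (exactly collinear axes would make the torsion 0/0),
    while staying small enough that a pure twist leaks less than ~2
    degrees into the apparent bend. Twist rotates domain B about the
    inter-centroid axis, bend opens it about a perpendicular hinge axis
    through the linker region, so planted values are recovered exactly by
    construction (up to the dihedral jitter). Ground truth and the domain
    split live in ``structure.metadata``.
    """
    if n_res_per_domain < 20:
        raise IgtandemError("need >= 20 residues per domain")
    if len(linker) != 2 or any(c not in AA1_TO_3 for c in linker.upper()):
        raise IgtandemError(f"linker must be 2 one-letter codes, got {linker!r}")
    if not (-180.0 < twist <= 180.0):
        raise IgtandemError(f"twist {twist} outside (-180, 180]")
    if not (0.0 <= bend <= 180.0):
        raise IgtandemError(f"bend {bend} outside [0, 180]")
    rng = stream_rng(seed, "ig_tandem")
    n = n_res_per_domain

    dom = build_chain(_meander_spec(n, rng, dihedral_jitter, charged_poles))
    ca = np.array([r.atom("CA").coords for r in dom.all_residues(0)])
    coords = _structure_coords(dom)
    rot = Rotation.from_euler("y", tilt, degrees=True).as_matrix() @ _axis_to_z(ca)
    center = ca.mean(axis=0)
    coords_a = (coords - center) @ rot.T

    zmax, zmin = coords_a[:, 2].max(), coords_a[:, 2].min()
    # place B along +z so that the closest heavy-atom approach between the
    # domains equals ``gap`` (a van der Waals contact distance by default,
    # giving the tandem a genuine, limited set of interface contacts)
    from scipy.spatial import cKDTree

    tree_a = cKDTree(coords_a)

    def min_cross(rise_try: float) -> float:
        d, _ = tree_a.query(coords_a + np.array([0.0, 0.0, rise_try]))
        return float(d.min())

    lo, hi = 0.0, 2.0 * (zmax - zmin) + 10.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_cross(mid) < gap:
            lo = mid
        else:
            hi = mid
    rise = hi
    hinge = np.array([0.0, 0.0, 0.5 * (zmax + zmin + rise)])
    r_twist = Rotation.from_euler("z", twist, degrees=True).as_matrix()
    r_bend = Rotation.from_euler("y", bend, degrees=True).as_matrix()
    coords_b = coords_a @ r_twist.T + np.array([0.0, 0.0, rise])
    coords_b = (coords_b - hinge) @ r_bend.T + hinge

    link = build_chain([(AA1_TO_3[c], -130.0, 140.0, 180.0)
                        for c in linker.upper()])
    lc = _structure_coords(link)
    lca = np.array([r.atom("CA").coords for r in link.all_residues(0)])
    lc = (lc - lca.mean(axis=0)) @ _axis_to_z(lca).T + hinge

    residues: list[Residue] = []
    atom_coords = [coords_a, lc, coords_b]
    sources = [dom, link, dom]
    number = 1
    for src, block in zip(sources, atom_coords):
        k = 0
        for r in src.all_residues(0):
            atoms = []
            for a in r.atoms:
                from .structure import Atom
                atoms.append(Atom(a.name, a.element, block[k], a.occupancy))
                k += 1
            residues.append(Residue("A", number, "", r.aa3, atoms))
            number += 1

    split = DomainSplit({"I10": ("A", 1, n),
                         "linker": ("A", n + 1, n + 2),
                         "I11": ("A", n + 3, 2 * n + 2)})
    st = Structure([{"A": residues}], id="synthetic-ig-tandem")
    st.metadata["split"] = split
    st.metadata["ground_truth"] = {
        "twist": twist, "bend": bend, "tilt": tilt, "rise": rise,
        "hinge": hinge, "axis": np.array([0.0, 0.0, 1.0]),
        "bend_axis": np.array([0.0, 1.0, 0.0]),
        "n_res_per_domain": n, "seed": seed,
    }
    return st


# ---------------------------------------------------------------------------
# Rigid-body hinge trajectories


def gen_trajectory(base: Structure, twist_range: float = 0.0,
                   bend_range: float = 0.0, n_frames: int = 50,
                   noise_sd: float = 0.1, seed: int = 0,
                   twist_center: float = 0.0,
                   bend_center: float | None = None,
                   group: str = "wt") -> TrajectoryEnsemble:
    """Rigid-body hinge trajectory of a two-domain tandem.

    Domain B oscillates sinusoidally about the linker hinge: twist samples
    ``twist_center +/- twist_range/2`` about the inter-centroid axis and
    bend ``[0, bend_range]`` (or ``bend_center +/- bend_range/2``) about
    the perpendicular hinge axis, at incommensurate frequencies so the two
    modes decorrelate. Sinusoidal (arcsine-distributed) sampling mirrors
    oscillation along a mode and puts the sampled extremes at the planted
    range, so percentile-based range estimates recover it. Isotropic
    Gaussian noise of ``noise_sd`` (A) is added to every coordinate.
    Per-frame ground-truth angles are stored in ``metadata``.
    """
    if n_frames < 2:
        raise IgtandemError("need >= 2 frames")
    meta = base.metadata
    if "split" not in meta or "ground_truth" not in meta:
        raise IgtandemError(
            "base must be a two-domain structure with split metadata "
            "(as produced by gen_ig_tandem)")
    if meta["ground_truth"]["bend"] != 0.0:
        raise IgtandemError("trajectory base must be built with bend = 0")
    split: DomainSplit = meta["split"]
    hinge = np.asarray(meta["ground_truth"]["hinge"], float)
    rng = stream_rng(seed, f"trajectory:{group}")
    if bend_center is None:
        bend_center = bend_range / 2.0

    labels = [(r.chain_id, r.number, r.insertion_code, r.aa3, a.name)
              for r in base.all_residues(0) for a in r.atoms]
    base_coords = _structure_coords(base)
    chain_b, b0, b1 = split.ranges["I11"]
    b_idx = np.array([k for k, (cid, num, _ic, _aa, _an) in enumerate(labels)
                      if cid == chain_b and b0 <= num <= b1])

    phase_t, phase_b = rng.uniform(0, 2 * np.pi, 2)
    j = np.arange(n_frames)
    twists = twist_center + (twist_range / 2.0) * np.sin(
        2 * np.pi * 2 * j / n_frames + phase_t)
    bends = bend_center + (bend_range / 2.0) * np.sin(
        2 * np.pi * 3 * j / n_frames + phase_b)

    frames = np.empty((n_frames, len(labels), 3))
    for f in range(n_frames):
        coords = base_coords.copy()
        rt = Rotation.from_euler("z", twists[f], degrees=True).as_matrix()
        rb = Rotation.from_euler("y", bends[f], degrees=True).as_matrix()
        b = coords[b_idx] @ rt.T
        b = (b - hinge) @ rb.T + hinge
        coords[b_idx] = b
        frames[f] = coords
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)

    ens = TrajectoryEnsemble(frames, labels, [group] * n_frames,
                             [f"synthetic:{group}[{i}]"
                              for i in range(n_frames)])
    ens.metadata["ground_truth"] = {
        "twist_range": twist_range, "bend_range": bend_range,
        "twist_center": twist_center, "bend_center": bend_center,
        "noise_sd": noise_sd, "seed": seed,
        "twists": twists, "bends": bends,
    }
    ens.metadata["split"] = split
    return ens


# ---------------------------------------------------------------------------
# Beta-turn libraries


def _largest_remainder_counts(freqs: dict[str, float], n: int,
                              pool: list[str]) -> list[str]:
    """Deterministic per-position residue multiset realizing ``freqs``;
    leftover probability mass is spread uniformly over unlisted residues."""
    rest = [aa for aa in pool if aa not in freqs]
    leftover = 1.0 - sum(freqs.values())
    if leftover < -1e-9:
        raise IgtandemError(f"composition frequencies sum to > 1: {freqs}")
    full = dict(freqs)
    for aa in rest:
        full[aa] = leftover / len(rest) if rest else 0.0
    quotas = {aa: f * n for aa, f in full.items()}
    counts = {aa: int(np.floor(q)) for aa, q in quotas.items()}
    short = n - sum(counts.values())
    order = sorted(quotas, key=lambda aa: (-(quotas[aa] - counts[aa]), aa))
    for aa in order[:short]:
        counts[aa] += 1
    out: list[str] = []
    for aa in sorted(counts):
        out.extend([aa] * counts[aa])
    return out


def gen_turn_library(composition: dict[str, dict[str, float]] | None = None,
                     n_turns: int = 100, turn_type: str = "II",
                     seed: int = 0, jitter: float = 5.0
                     ) -> tuple[list[Structure], dict]:
    """Short chains each embedding one turn of the requested type.

    ``composition`` maps turn positions ("i", "i+1", "i+2", "i+3") to
    per-residue frequency dicts; counts are realized by deterministic
    largest-remainder rounding, then shuffled. Turn dihedrals are the
    canonical values for ``turn_type`` +/- ``jitter`` (uniform). Four-mer
    sequences are kept unique (bounded in-position swaps, which preserve
    the planted counts) so a uniqueness-deduplicated survey sees every
    planted turn. Returns (structures, ground_truth).
    """
    if turn_type not in CANONICAL_TURN_DIHEDRALS:
        raise IgtandemError(f"unknown turn type {turn_type!r}")
    composition = composition or {}
    rng = stream_rng(seed, "turn_library")
    positions = ("i", "i+1", "i+2", "i+3")
    for pos in composition:
        if pos not in positions:
            raise IgtandemError(f"unknown turn position {pos!r}")
    if n_turns == 0:
        return [], {"sequences": [], "counts": {}}

    pools: dict[str, list[str]] = {}
    for pos in positions:
        pool = _largest_remainder_counts(composition.get(pos, {}), n_turns,
                                         ALL_AA3)
        rng.shuffle(pool)
        pools[pos] = pool

    seqs: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    for t in range(n_turns):
        seq = tuple(pools[p][t] for p in positions)
        attempts = 0
        while seq in seen and attempts < 200:
            # swap within a position's remaining pool: counts preserved
            pos = positions[int(rng.integers(0, 4))]
            if t + 1 < n_turns:
                other = int(rng.integers(t + 1, n_turns))
                pools[pos][t], pools[pos][other] = (pools[pos][other],
                                                    pools[pos][t])
                seq = tuple(pools[p][t] for p in positions)
            attempts += 1
        seen.add(seq)
        seqs.append(seq)

    canon = CANONICAL_TURN_DIHEDRALS[turn_type]
    strand = (-120.0, 130.0)
    structures: list[Structure] = []
    for t, seq in enumerate(seqs):
        flank = [ALL_AA3[int(rng.integers(0, 20))] for _ in range(4)]
        names = [flank[0], flank[1], seq[0], seq[1], seq[2], seq[3],
                 flank[2], flank[3]]
        phi1 = canon[0] + rng.uniform(-jitter, jitter)
        psi1 = canon[1] + rng.uniform(-jitter, jitter)
        phi2 = canon[2] + rng.uniform(-jitter, jitter)
        psi2 = canon[3] + rng.uniform(-jitter, jitter)
        dihedrals = [strand, strand, strand, (phi1, psi1), (phi2, psi2),
                     strand, strand, strand]
        spec = [(nm, ph, ps, 180.0) for nm, (ph, ps) in zip(names, dihedrals)]
        st = build_chain(spec)
        st.metadata["turn_sequence"] = seq
        st.metadata["turn_type"] = turn_type
        structures.append(st)

    counts: dict[str, dict[str, int]] = {}
    for p_i, pos in enumerate(positions):
        c: dict[str, int] = {}
        for seq in seqs:
            c[seq[p_i]] = c.get(seq[p_i], 0) + 1
        counts[pos] = c
    truth = {"sequences": ["".join(AA3_TO_1[a] for a in s) for s in seqs],
             "counts": counts, "turn_type": turn_type, "seed": seed}
    return structures, truth


# ---------------------------------------------------------------------------
# HSQC peak lists


def gen_peaklists(n_res: int = 91, planted=None, noise_sd_ppm: float = 0.0,
                  seed: int = 0, w_n: float = 0.2, n_fraction: float = 0.0
                  ) -> tuple[PeakList, PeakList, dict]:
    """A wild-type/mutant HSQC peak-list pair with planted perturbations.

    ``planted`` is a list of (residue, target Ddelta_AV in ppm, direction)
    tuples (direction +/-1, optional). The displacement goes entirely into
    deltaH by default, so the planted Ddelta_AV is exact regardless of the
    nitrogen weight; ``n_fraction`` moves that fraction of the squared
    perturbation into deltaN (scaled by 1/w_n). Gaussian noise of
    ``noise_sd_ppm`` is added to the mutant list after planting.
    """
    import pandas as pd

    rng = stream_rng(seed, "peaklists")
    planted = planted or []
    res = np.arange(1, n_res + 1)
    wt = pd.DataFrame({
        "residue": res,
        "dH": np.round(rng.uniform(6.5, 9.8, n_res), 3),
        "dN": np.round(rng.uniform(105.0, 130.0, n_res), 2),
    })
    mut = wt.copy()
    seen: set[int] = set()
    truth: dict[int, float] = {}
    for item in planted:
        r, target = int(item[0]), float(item[1])
        direction = float(item[2]) if len(item) > 2 else 1.0
        if r in seen:
            raise IgtandemError(f"residue {r} planted twice")
        seen.add(r)
        if not 1 <= r <= n_res:
            raise IgtandemError(f"planted residue {r} outside 1..{n_res}")
        if target < 0:
            raise IgtandemError(f"negative CSP target for residue {r}")
        dh = target * np.sqrt(1.0 - n_fraction)
        dn = target * np.sqrt(n_fraction) / w_n
        row = mut.index[mut["residue"] == r][0]
        mut.loc[row, "dH"] += np.sign(direction) * dh
        mut.loc[row, "dN"] += np.sign(direction) * dn
        truth[r] = target
    if noise_sd_ppm > 0:
        mut["dH"] += rng.normal(0, noise_sd_ppm, n_res)
        mut["dN"] += rng.normal(0, noise_sd_ppm, n_res)
    gt = {"planted": truth, "noise_sd_ppm": noise_sd_ppm, "w_n": w_n,
          "n_fraction": n_fraction, "seed": seed}
    return (PeakList(wt, "wt"), PeakList(mut, "mut"), gt)


# ---------------------------------------------------------------------------
# Melting curves


def gen_melting_curve(tm: float = 62.3, k: float = 1.5,
                      baselines: tuple[tuple[float, float],
                                       tuple[float, float]] = ((1000.0, 2.0),
                                                               (9000.0, -5.0)),
                      noise_frac: float = 0.0,
                      t_range: tuple[float, float] = (25.0, 95.0),
                      step: float = 0.5, seed: int = 0,
                      label: str = "") -> tuple[MeltingCurve, dict]:
    """Boltzmann sigmoid melt curve with linear baselines and noise.

    ``noise_frac`` is the Gaussian noise SD as a fraction of the
    transition amplitude at Tm (0.02 = "2% noise"). Tm must lie inside
    ``t_range``.
    """
    lo, hi = t_range
    if not lo < tm < hi:
        raise IgtandemError(f"tm {tm} outside range {t_range}")
    if k <= 0:
        raise IgtandemError("slope k must be positive")
    rng = stream_rng(seed, f"melting:{label}")
    t = np.arange(lo, hi + step / 2, step)
    (a1, b1), (a2, b2) = baselines
    f = boltzmann(t, tm, k, a1, b1, a2, b2)
    amplitude = abs((a2 + b2 * tm) - (a1 + b1 * tm))
    if noise_frac > 0:
        f = f + rng.normal(0.0, noise_frac * amplitude, len(t))
    gt = {"tm": tm, "k": k, "baselines": baselines,
          "noise_frac": noise_frac, "seed": seed}
    return MeltingCurve(t, f, label), gt
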