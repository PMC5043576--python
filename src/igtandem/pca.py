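"""Covariance (essential-dynamics) analysis of conformational ensembles.

Frames from all groups are concatenated and fitted on a reference atom
subset (typically the backbone of one domain, which isolates interdomain
motion), then the mass-unweighted Cartesian covariance of the selected
coordinates is eigendecomposed. Numerically the eigenpairs come from an
economy SVD of the centered frames x 3N matrix, which is identical to
diagonalizing the 3N x 3N covariance but far cheaper when frames << 3N.
Leading modes describe dominant collective motions; for an Ig tandem the
twist (rotation of one domain about the inter-domain axis) and bend
(opening between domain axes) are recovered per mode by measuring the
interdomain geometry of the mode's extreme conformations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, IgtandemError
from .geometry import kabsch_superpose, wrap_angle
from .interface import interdomain_geometry_ca
from .structure import DomainSplit, TrajectoryEnsemble


def superpose_ensemble(ens: TrajectoryEnsemble,
                       ref_indices: np.ndarray,
                       ref_frame: int = 0) -> TrajectoryEnsemble:
    """Kabsch-fit every frame onto the reference frame using the atoms in
    ``ref_indices``; the rigid transform is applied to all atoms."""
    ref_indices = np.asarray(ref_indices, dtype=int)
    if ref_indices.size < 3:
        raise DegenerateGeometryError(
            f"reference selection has {ref_indices.size} atoms, need >= 3")
    target = ens.coords[ref_frame][ref_indices]
    out = np.empty_like(ens.coords)
    for f in range(ens.n_frames):
        sup = kabsch_superpose(ens.coords[f][ref_indices], target)
        out[f] = sup.apply(ens.coords[f])
    return TrajectoryEnsemble(out, ens.atom_labels, list(ens.groups),
                              list(ens.sources), dict(ens.metadata))


@dataclass
class PCResult:
    """Eigenvectors/eigenvalues of the coordinate covariance plus per-frame
    projections. Eigenvalues are in A^2, descending; eigenvector signs are
    fixed deterministically (largest-magnitude component positive)."""

    mean: np.ndarray              # (3n,)
    eigenvectors: np.ndarray      # (modes, 3n)
    eigenvalues: np.ndarray       # (modes,)
    projections: np.ndarray       # (frames, modes)
    variance_fractions: np.ndarray
    atom_indices: np.ndarray      # selection into the ensemble's atoms
    ensemble: TrajectoryEnsemble = field(repr=False)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    @property
    def groups(self) -> list[str]:
        return self.ensemble.groups

    def reconstruct(self, mode: int, projection: float) -> np.ndarray:
        """Coordinates (n_sel, 3) of mean + projection * eigenvector."""
        flat = self.mean + projection * self.eigenvectors[mode]
        return flat.reshape(-1, 3)


def covariance_pca(ens: TrajectoryEnsemble,
                   selection: np.ndarray | None = None,
                   n_modes: int | None = None) -> PCResult:
    """PCA of the (mass-unweighted) Cartesian covariance of a superposed
    ensemble. Groups must be concatenated beforehand so they share one
    basis. At most frames-1 modes carry variance; requesting more warns and
    truncates."""
    if ens.n_frames < 2:
        raise IgtandemError("PCA needs at least 2 frames")
    idx = (np.arange(ens.n_atoms) if selection is None
           else np.asarray(selection, dtype=int))
    x = ens.coords[:, idx, :].reshape(ens.n_frames, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    available = min(ens.n_frames - 1, xc.shape[1])
    if n_modes is None:
        n_modes = available
    elif n_modes > available:
        warnings.warn(f"requested {n_modes} modes but only {available} carry "
                      "variance; truncating", stacklevel=2)
        n_modes = available
    eigvals = (s ** 2) / (ens.n_frames - 1)
    total = eigvals.sum()
    # deterministic sign: the largest-|component| of each eigenvector is
    # made positive (ties resolve to the first such index)
    signs = np.ones(len(s))
    for m in range(len(s)):
        k = int(np.argmax(np.abs(vt[m])))
        if vt[m, k] < 0:
            signs[m] = -1.0
    vt = vt * signs[:, None]
    proj = xc @ vt.T
    return PCResult(
        mean=mean,
        eigenvectors=vt[:n_modes],
        eigenvalues=eigvals[:n_modes],
        projections=proj[:, :n_modes],
        variance_fractions=(eigvals[:n_modes] / total if total > 0
                            else np.zeros(n_modes)),
        atom_indices=idx,
        ensemble=ens,
    )


@dataclass
class ModeAngles:
    """Interdomain twist/bend swing of one principal mode, measured between
    the mode's two extreme conformations."""

    mode: int
    twist_range: float  # deg
    bend_range: float   # deg
    torsions: tuple[float, float]
    bends: tuple[float, float]
    method: str
    projections: tuple[float, float]


def _domain_ca_from_selection(pc: PCResult, split: DomainSplit,
                              names: tuple[str, str]):
    """Indices of each domain's CA atoms inside the PCA selection."""
    labels = [pc.ensemble.atom_labels[i] for i in pc.atom_indices]
    out = []
    for name in names:
        chain, a, b = split.ranges[name]
        rows = [k for k, (cid, num, _ic, _aa, aname) in enumerate(labels)
                if aname == "CA" and cid == chain and a <= num <= b]
        if len(rows) < 3:
            raise IgtandemError(
                f"domain {name}: PCA selection contains {len(rows)} CA atoms")
        out.append(np.array(rows, dtype=int))
    return out


def mode_angles(pc: PCResult, mode: int, split: DomainSplit,
                method: str = "frames",
                percentiles: tuple[float, float] = (2.5, 97.5),
                n_average: int = 3,
                domain_a: str | None = None, domain_b: str | None = None
                ) -> ModeAngles:
    """Twist and bend range described by one principal component.

    The two extreme conformations along the mode are taken at the given
    projection percentiles (2.5/97.5 by default, damping outliers). With
    ``method="frames"`` (default) they are the ``n_average`` trajectory
    frames nearest each extreme projection, coordinate-averaged to damp
    per-frame noise, so large rotations are measured faithfully;
    ``method="reconstruct"`` instead displaces the mean along the linear
    eigenvector, which is the textbook construction but provably shrinks
    large rotation amplitudes (chord vs arc). Each extreme is reduced to
    its interdomain geometry; twist range = |delta torsion|, bend range =
    |delta bend|.
    """
    if not 0 <= mode < pc.n_modes:
        raise IgtandemError(f"mode {mode} out of range (have {pc.n_modes})")
    if method not in ("frames", "reconstruct"):
        raise ValueError(f"unknown method {method!r}")
    names = split.domain_names()
    if domain_a is None or domain_b is None:
        if len(names) < 2:
            raise IgtandemError("split must name two domains")
        domain_a, domain_b = names[0], names[-1]
    p = pc.projections[:, mode]
    lo, hi = np.percentile(p, percentiles)
    idx_a, idx_b = _domain_ca_from_selection(pc, split, (domain_a, domain_b))

    # a mode with no projection spread has no motion to measure
    scale = max(float(np.abs(p).max()), 1.0)
    if hi - lo <= 1e-9 * scale:
        return ModeAngles(mode, 0.0, 0.0, (0.0, 0.0), (0.0, 0.0), method,
                          (float(lo), float(hi)))

    geoms = []
    extremes = (lo, hi)
    for target in extremes:
        if method == "frames":
            order = np.argsort(np.abs(p - target))[:max(1, n_average)]
            coords = pc.ensemble.coords[order][:, pc.atom_indices].mean(axis=0)
        else:
            coords = pc.reconstruct(mode, target)
        geoms.append(interdomain_geometry_ca(coords[idx_a], coords[idx_b]))
    twist = abs(float(wrap_angle(geoms[1].torsion - geoms[0].torsion)))
    bend = abs(geoms[1].bend - geoms[0].bend)
    return ModeAngles(mode, twist, bend,
                      (geoms[0].torsion, geoms[1].torsion),
                      (geoms[0].bend, geoms[1].bend),
                      method, (float(lo), float(hi)))


@dataclass
class ComparisonReport:
    """Group-wise statistics of principal-component projections."""

    stats: pd.DataFrame          # group, mode, n, mean, sd
    separations: dict[int, float]  # per mode: (m1 - m2) / pooled sd
    overlaps: dict[int, float]     # per mode: histogram overlap in [0, 1]
    histograms: dict[int, dict[str, np.ndarray]]
    bin_edges: dict[int, np.ndarray]
    orientation: np.ndarray      # sign applied per mode


def compare_ensembles(pc: PCResult, groups: list[str] | None = None,
                      modes: int = 3, bins: int = 20) -> ComparisonReport:
    """Compare conformational sampling of labelled groups in PC space.

    Modes are oriented so the first group's mean projection is positive
    (so "more positive on PC1" is a stable, reportable convention). The
    separation statistic is the difference of the first two groups' means
    in units of their pooled SD; the overlap coefficient is the shared area
    of the two normalized projection histograms.
    """
    labels = np.asarray(pc.groups)
    if groups is None:
        groups = list(dict.fromkeys(pc.groups))
    if len(groups) < 2:
        raise IgtandemError("need at least 2 groups to compare")
    for g in groups:
        if int((labels == g).sum()) < 2:
            raise IgtandemError(f"group {g!r} has fewer than 2 frames")
    modes = min(modes, pc.n_modes)
    proj = pc.projections[:, :modes].copy()
    first = labels == groups[0]
    orientation = np.where(proj[first].mean(axis=0) < 0, -1.0, 1.0)
    proj *= orientation

    rows = []
    separations: dict[int, float] = {}
    overlaps: dict[int, float] = {}
    histograms: dict[int, dict[str, np.ndarray]] = {}
    edges_out: dict[int, np.ndarray] = {}
    for m in range(modes):
        per_group = {g: proj[labels == g, m] for g in groups}
        for g, v in per_group.items():
            rows.append({"group": g, "mode": m + 1, "n": len(v),
                         "mean": float(v.mean()),
                         "sd": float(v.std(ddof=1))})
        v1, v2 = per_group[groups[0]], per_group[groups[1]]
        pooled = np.sqrt(((len(v1) - 1) * v1.var(ddof=1)
                          + (len(v2) - 1) * v2.var(ddof=1))
                         / (len(v1) + len(v2) - 2))
        separations[m + 1] = float((v1.mean() - v2.mean())
                                   / pooled) if pooled > 0 else 0.0
        edges = np.histogram_bin_edges(proj[:, m], bins=bins)
        hists = {g: np.histogram(v, bins=edges)[0] / max(len(v), 1)
                 for g, v in per_group.items()}
        h1, h2 = hists[groups[0]], hists[groups[1]]
        overlaps[m + 1] = float(np.minimum(h1, h2).sum())
        histograms[m + 1] = hists
        edges_out[m + 1] = edges
    return ComparisonReport(pd.DataFrame(rows), separations, overlaps,
                            histograms, edges_out, orientation)
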