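"""NMR statistics: chemical-shift perturbations, R2/R1 relaxation flags and
the Karplus phi - 3J comparison.

The CSP statistic is the weighted average difference between two HSQC peak
lists, Ddelta_AV = sqrt(DdeltaH^2 + (w_N * DdeltaN)^2) with w_N = 0.2 by
default (the common 15N scaling; configurable). Perturbations are classed
"moderate" (0.03 < Ddelta_AV < 0.15 ppm) or "large" (Ddelta_AV > 0.15 ppm);
values exactly on a threshold fall to the lower class. Elevated R2/R1
ratios flag residues in slow (us-ms) conformational exchange; the "above
average" rule is hardened to a trimmed mean + k*SD threshold so the flagged
residues themselves do not drag the baseline up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IgtandemError

CSP_CLASSES = ("none", "moderate", "large", "unassigned")


@dataclass
class PeakList:
    """Per-residue amide peak positions (residue number, deltaH, deltaN in
    ppm) for one sample."""

    data: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        required = {"residue", "dH", "dN"}
        if not required.issubset(self.data.columns):
            raise IgtandemError(f"peak list needs columns {sorted(required)}")
        self.data = self.data.reset_index(drop=True)
        if self.data["residue"].duplicated().any():
            dups = self.data.loc[self.data["residue"].duplicated(), "residue"]
            raise IgtandemError(
                f"duplicate residues in peak list {self.label!r}: "
                f"{sorted(set(dups))}")
        if not np.all(np.isfinite(self.data[["dH", "dN"]].to_numpy())):
            raise IgtandemError(f"non-finite shifts in peak list {self.label!r}")

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "PeakList":
        return cls(pd.read_csv(path, sep="\t"), label or str(path))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass
class CSPTable:
    """Per-residue Ddelta_AV with class labels."""

    data: pd.DataFrame  # residue, d_av, csp_class
    w_n: float
    thresholds: tuple[float, float]

    def counts(self) -> dict[str, int]:
        c = self.data["csp_class"].value_counts().to_dict()
        return {k: int(c.get(k, 0)) for k in CSP_CLASSES}

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


#: values within this of a threshold count as *at* it (lower class); guards
#: the strict > inequality against float rounding of ppm arithmetic
_THRESHOLD_EPS = 1e-9


def _assign_classes(d_av: pd.Series, moderate: float, large: float) -> pd.Series:
    def one(x):
        if not np.isfinite(x):
            return "unassigned"
        if x > large + _THRESHOLD_EPS:
            return "large"
        if x > moderate + _THRESHOLD_EPS:  # boundary -> lower class
            return "moderate"
        return "none"

    return d_av.map(one)


def csp(wt: PeakList, mut: PeakList, w_n: float = 0.2,
        moderate: float = 0.03, large: float = 0.15) -> CSPTable:
    """Weighted-average chemical shift perturbation per residue.

    Residues present in only one list get NaN and class "unassigned".
    Symmetric in the (wt, mut) order.
    """
    merged = wt.data.merge(mut.data, on="residue", how="outer",
                           suffixes=("_wt", "_mut")).sort_values("residue")
    dh = merged["dH_mut"] - merged["dH_wt"]
    dn = merged["dN_mut"] - merged["dN_wt"]
    d_av = np.hypot(dh, w_n * dn)
    out = pd.DataFrame({"residue": merged["residue"].astype(int),
                        "d_av": d_av}).reset_index(drop=True)
    out["csp_class"] = _assign_classes(out["d_av"], moderate, large)
    return CSPTable(out, w_n, (moderate, large))


def classify_csp(table: CSPTable, moderate: float = 0.03,
                 large: float = 0.15) -> dict[str, int]:
    """(Re)classify a CSP table at the given thresholds and return class
    counts. Strict inequalities: large means d_av > ``large``, moderate
    means ``moderate`` < d_av <= ``large``."""
    if not 0 < moderate < large:
        raise IgtandemError(
            f"thresholds must satisfy 0 < moderate < large, got "
            f"{moderate}/{large}")
    table.data["csp_class"] = _assign_classes(table.data["d_av"],
                                              moderate, large)
    table.thresholds = (moderate, large)
    return table.counts()


@dataclass
class RelaxationTable:
    """Per-residue 15N R1/R2 rates with the R2/R1 ratio."""

    data: pd.DataFrame  # residue, r1, r2, ratio
    label: str = ""

    def __post_init__(self) -> None:
        required = {"residue", "r1", "r2"}
        if not required.issubset(self.data.columns):
            raise IgtandemError(f"relaxation table needs {sorted(required)}")
        self.data = self.data.reset_index(drop=True)
        vals = self.data[["r1", "r2"]].to_numpy(float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise IgtandemError("R1/R2 rates must be finite and positive")
        self.data["ratio"] = self.data["r2"] / self.data["r1"]

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "RelaxationTable":
        return cls(pd.read_csv(path, sep="\t"), label or str(path))


def r2r1_flags(table: RelaxationTable, k: float = 1.0,
               trim: tuple[float, float] = (5.0, 95.0)) -> pd.DataFrame:
    """Flag residues with R2/R1 above a robust baseline.

    The baseline mean and SD are computed on ratios inside the
    ``trim`` percentile band (default 5-95), so a handful of
    exchange-broadened residues cannot inflate their own threshold. A
    residue is flagged when ratio > mean + k*SD. Returns the table with a
    boolean ``flagged`` column; the threshold is stored in ``attrs``.
    """
    if len(table.data) < 5:
        raise IgtandemError("need >= 5 residues for R2/R1 statistics")
    ratios = table.data["ratio"].to_numpy(float)
    lo, hi = np.percentile(ratios, trim)
    core = ratios[(ratios >= lo) & (ratios <= hi)]
    mean, sd = float(core.mean()), float(core.std(ddof=1))
    threshold = mean + k * sd
    out = table.data.copy()
    out["flagged"] = out["ratio"] > threshold
    out.attrs["threshold"] = threshold
    out.attrs["trimmed_mean"] = mean
    out.attrs["trimmed_sd"] = sd
    return out


#: literature-style coefficients for 3J(C'_{k-1}, Halpha_k) in Hz; the
#: +120 deg phase maps positive-phi (alphaL) residues onto the large-J limb.
KARPLUS_DEFAULT = (3.72, -2.18, 1.28)
KARPLUS_PHASE_DEFAULT = 120.0


def karplus_j(phi, coeffs: tuple[float, float, float] = KARPLUS_DEFAULT,
              phase: float = KARPLUS_PHASE_DEFAULT):
    """Karplus relation J = A cos^2(phi + phase) + B cos(phi + phase) + C.

    ``phi`` may be a scalar, an array of degrees, or a DataFrame with a
    ``phi`` column (as produced by :func:`igtandem.geometry.phi_psi`), in
    which case a copy with a ``j_pred`` column is returned.
    """
    a, b, c = coeffs
    if isinstance(phi, pd.DataFrame):
        out = phi.copy()
        out["j_pred"] = karplus_j(out["phi"].to_numpy(float), coeffs, phase)
        return out
    theta = np.radians(np.asarray(phi, dtype=float) + phase)
    j = a * np.cos(theta) ** 2 + b * np.cos(theta) + c
    return float(j) if np.ndim(phi) == 0 else j
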