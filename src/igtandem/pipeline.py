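"""End-to-end report pipeline: configuration, stage orchestration, logging.

``run_report`` executes the configured subset of analysis stages on given
inputs (or on synthetic defaults when no inputs are configured), writes one
TSV per stage plus a combined summary, and echoes the resolved
configuration into the output directory so a run can be reproduced from
its own artifacts. Any stage failure raises :class:`StageError` naming the
stage; outputs of completed stages are preserved.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import interface, melting, nmr, pca, synthetic, turns
from .errors import IgtandemError, StageError
from .io import read_manifest, read_structure
from .structure import DomainSplit

log = logging.getLogger("igtandem")

STAGES = ("structure", "turns", "nmr", "dsf", "pca")


@dataclass
class RunConfig:
    """Fully serializable run configuration; defaults reproduce the
    all-synthetic demonstration run."""

    out_dir: str = "igtandem_report"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # optional input paths; None -> generate synthetically
    structure_path: str | None = None
    split: str | None = None           # e.g. "I10:A:1-60,I11:A:63-122"
    wt_peaks: str | None = None
    mut_peaks: str | None = None
    relaxation: str | None = None
    wt_melt: str | None = None
    mut_melt: str | None = None
    trajectory_manifest: str | None = None
    probe_residue: int | None = None   # burial probe (author numbering)
    # thresholds
    csp_moderate: float = 0.03
    csp_large: float = 0.15
    csp_weight_n: float = 0.2
    hbond_dmax: float = 3.5
    hbond_angmin: float = 120.0
    turn_ca_cutoff: float = 7.0
    r2r1_k: float = 1.0
    # synthetic-scenario parameters
    syn: dict = field(default_factory=lambda: {
        "n_res_per_domain": 90,
        "n_frames": 50,
        "twist_range": 30.0,
        "bend_range": 10.0,
        "twist_center_wt": 16.0,
        "twist_center_mut": -16.0,
        "noise_sd": 0.1,
        "n_turns": 100,
        "gly_i2_freq": 0.78,
        "n_res_nmr": 91,
        "n_large": 6,
        "n_moderate": 10,
        "large_ppm": 0.20,
        "moderate_ppm": 0.08,
        "tm_wt": 62.3,
        "tm_mut": 51.4,
        "melt_k": 1.5,
        "melt_noise_frac": 0.02,
    })

    def validate(self) -> None:
        if not 0 < self.csp_moderate < self.csp_large:
            raise IgtandemError("need 0 < csp_moderate < csp_large")
        if not 2.0 <= self.hbond_dmax <= 5.0:
            raise IgtandemError("hbond_dmax outside sane range 2-5 A")
        if not 90.0 <= self.hbond_angmin <= 180.0:
            raise IgtandemError("hbond_angmin outside 90-180 deg")
        if not 4.0 <= self.turn_ca_cutoff <= 12.0:
            raise IgtandemError("turn_ca_cutoff outside 4-12 A")
        for s in self.stages:
            if s not in STAGES:
                raise IgtandemError(f"unknown stage {s!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise IgtandemError(f"unknown config key {k!r}")
            if k in ("stages", "syn"):
                getattr(cfg, k).update(v)
            else:
                setattr(cfg, k, v)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _check_inputs(cfg: RunConfig) -> None:
    for name in ("structure_path", "wt_peaks", "mut_peaks", "relaxation",
                 "wt_melt", "mut_melt", "trajectory_manifest"):
        p = getattr(cfg, name)
        if p is not None and not os.path.exists(p):
            raise StageError(f"input: missing input file for {name}: {p}")


def _fmt(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_report(config: RunConfig) -> dict:
    """Run the configured stages; return the summary dict.

    Per-stage TSVs, ``summary.tsv`` and the echoed ``config.yaml`` land in
    ``config.out_dir``.
    """
    config.validate()
    _check_inputs(config)
    os.makedirs(config.out_dir, exist_ok=True)
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
    logfile = os.path.join(config.out_dir, "run.log")
    handler = logging.FileHandler(logfile)
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    summary: dict = {}
    syn = config.syn
    try:
        structure = None
        split = None
        if any(config.stages.get(s) for s in ("structure", "pca")):
            if config.structure_path:
                structure = read_structure(config.structure_path)
                if not config.split:
                    raise StageError("structure: a --split is required with "
                                     "an input structure")
                split = DomainSplit.parse(config.split)
            else:
                structure = synthetic.gen_ig_tandem(
                    n_res_per_domain=syn["n_res_per_domain"],
                    seed=config.seed)
                split = structure.metadata["split"]

        for stage, fn in (("structure", _stage_structure),
                          ("turns", _stage_turns),
                          ("nmr", _stage_nmr),
                          ("dsf", _stage_dsf),
                          ("pca", _stage_pca)):
            if not config.stages.get(stage, False):
                log.info("stage %s: disabled", stage)
                continue
            t0 = time.time()
            try:
                fn(config, structure, split, summary)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"{stage}: {exc}") from exc
            log.info("stage %s: done in %.2f s", stage, time.time() - t0)

        rows = [{"key": k, "value": v} for k, v in summary.items()]
        _fmt(pd.DataFrame(rows), os.path.join(config.out_dir, "summary.tsv"))
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage_structure(cfg: RunConfig, structure, split, summary: dict) -> None:
    out = cfg.out_dir
    bonds = interface.find_hbonds(structure, cfg.hbond_dmax, cfg.hbond_angmin)
    _fmt(pd.DataFrame([{
        "donor_chain": b.donor[0], "donor_res": b.donor[1],
        "donor_aa": b.donor[2], "donor_atom": b.donor[3],
        "acc_chain": b.acceptor[0], "acc_res": b.acceptor[1],
        "acc_aa": b.acceptor[2], "acc_atom": b.acceptor[3],
        "distance": b.distance, "donor_angle": b.donor_angle,
    } for b in bonds]), os.path.join(out, "hbonds.tsv"))
    summary["n_hbonds"] = len(bonds)

    contacts = interface.interface_contacts(structure, split)
    _fmt(pd.DataFrame([{
        "res_a": f"{c.residue_a[0]}:{c.residue_a[1]}", "aa_a": c.residue_a[2],
        "res_b": f"{c.residue_b[0]}:{c.residue_b[1]}", "aa_b": c.residue_b[2],
        "min_distance": c.min_distance, "kind": c.kind,
    } for c in contacts]), os.path.join(out, "contacts.tsv"))
    summary["n_interface_contacts"] = len(contacts)

    geom = interface.interdomain_geometry(structure, split)
    summary["torsion_deg"] = round(geom.torsion, 2)
    summary["bend_deg"] = round(geom.bend, 2)
    summary["rise_A"] = round(geom.rise, 2)

    poles = interface.pole_charges(structure, split)
    for name, (npole, cpole) in poles.items():
        summary[f"pole_charge_{name}"] = f"N:{npole:+d} C:{cpole:+d}"

    probe = cfg.probe_residue
    if probe is None:
        # default probe: last residue of the first domain (near interface)
        first = split.domain_names()[0]
        probe = split.ranges[first][2]
    chain = split.ranges[split.domain_names()[0]][0]
    try:
        summary["burial_fraction"] = round(
            interface.burial_fraction(structure, split, (chain, probe)), 3)
        summary["burial_probe"] = f"{chain}:{probe}"
    except IgtandemError as exc:
        log.info("burial skipped: %s", exc)
        summary["burial_fraction"] = "n/a"


def _stage_turns(cfg: RunConfig, structure, split, summary: dict) -> None:
    out = cfg.out_dir
    if structure is not None:
        found = turns.detect_turns(structure, cfg.turn_ca_cutoff)
        _fmt(pd.DataFrame([{
            "chain": t.chain, "start": t.residues[0][0], "type": t.type,
            "sequence": t.sequence, "ca_distance": t.ca_distance,
            "phi1": t.dihedrals[0], "psi1": t.dihedrals[1],
            "phi2": t.dihedrals[2], "psi2": t.dihedrals[3],
        } for t in found]), os.path.join(out, "turns.tsv"))
        summary["n_turns"] = len(found)
        if found:
            site = found[0]
            summary["turn_at_site"] = f"{site.chain}:{site.residues[0][0]} " \
                                      f"type {site.type}"
            region = turns.rama_region(site.dihedrals[2], site.dihedrals[3])
            summary["site_i2_region"] = region.label
            summary["site_i2_alphaL"] = region.alphaL
    lib, truth = synthetic.gen_turn_library(
        composition={"i+2": {"GLY": cfg.syn["gly_i2_freq"]}},
        n_turns=cfg.syn["n_turns"], seed=cfg.seed)
    table = turns.propensity_survey(lib, turn_type="II")
    table.to_tsv(os.path.join(out, "propensity.tsv"))
    gly = int(table.counts.loc["GLY", "i+2"])
    summary["survey_turns"] = table.total
    summary["survey_gly_i2"] = f"{gly}/{table.total}"


def _stage_nmr(cfg: RunConfig, structure, split, summary: dict) -> None:
    out = cfg.out_dir
    syn = cfg.syn
    if cfg.wt_peaks and cfg.mut_peaks:
        wt = nmr.PeakList.from_tsv(cfg.wt_peaks, "wt")
        mut = nmr.PeakList.from_tsv(cfg.mut_peaks, "mut")
    else:
        n = syn["n_res_nmr"]
        rng = synthetic.stream_rng(cfg.seed, "report:csp_sites")
        sites = rng.choice(np.arange(2, n), size=syn["n_large"]
                           + syn["n_moderate"], replace=False)
        planted = ([(int(r), syn["large_ppm"]) for r in sites[:syn["n_large"]]]
                   + [(int(r), syn["moderate_ppm"])
                      for r in sites[syn["n_large"]:]])
        wt, mut, _gt = synthetic.gen_peaklists(n, planted, seed=cfg.seed,
                                               w_n=cfg.csp_weight_n)
    table = nmr.csp(wt, mut, w_n=cfg.csp_weight_n,
                    moderate=cfg.csp_moderate, large=cfg.csp_large)
    counts = nmr.classify_csp(table, cfg.csp_moderate, cfg.csp_large)
    table.to_tsv(os.path.join(out, "csp.tsv"))
    summary["csp_large"] = counts["large"]
    summary["csp_moderate"] = counts["moderate"]

    if cfg.relaxation:
        rel = nmr.RelaxationTable.from_tsv(cfg.relaxation)
        flags = nmr.r2r1_flags(rel, k=cfg.r2r1_k)
        _fmt(flags, os.path.join(out, "relaxation.tsv"))
        summary["r2r1_flagged"] = int(flags["flagged"].sum())


def _stage_dsf(cfg: RunConfig, structure, split, summary: dict) -> None:
    out = cfg.out_dir
    syn = cfg.syn
    if cfg.wt_melt and cfg.mut_melt:
        wt_curve = melting.MeltingCurve.from_tsv(cfg.wt_melt, "wt")
        mut_curve = melting.MeltingCurve.from_tsv(cfg.mut_melt, "mut")
    else:
        wt_curve, _ = synthetic.gen_melting_curve(
            tm=syn["tm_wt"], k=syn["melt_k"],
            noise_frac=syn["melt_noise_frac"], seed=cfg.seed, label="wt")
        mut_curve, _ = synthetic.gen_melting_curve(
            tm=syn["tm_mut"], k=syn["melt_k"],
            noise_frac=syn["melt_noise_frac"], seed=cfg.seed, label="mut")
    fit_wt = melting.fit_melting(wt_curve)
    fit_mut = melting.fit_melting(mut_curve)
    dtm, dtm_err = melting.delta_tm(fit_wt, fit_mut)
    _fmt(pd.DataFrame([
        {"sample": f.label, "tm": f.tm, "tm_stderr": f.tm_stderr, "k": f.k,
         "rms": f.rms, "tm_derivative_peak": f.tm_derivative_peak}
        for f in (fit_wt, fit_mut)
    ]), os.path.join(out, "melt_fits.tsv"))
    summary["tm_wt"] = round(fit_wt.tm, 2)
    summary["tm_mut"] = round(fit_mut.tm, 2)
    summary["delta_tm"] = round(dtm, 2)
    summary["delta_tm_err"] = round(dtm_err, 2)


def _stage_pca(cfg: RunConfig, structure, split, summary: dict) -> None:
    out = cfg.out_dir
    syn = cfg.syn
    if cfg.trajectory_manifest:
        ens = read_manifest(cfg.trajectory_manifest)
        if split is None:
            raise StageError("pca: a --split is required with a manifest")
    else:
        wt = synthetic.gen_trajectory(
            structure, twist_range=syn["twist_range"],
            bend_range=syn["bend_range"], n_frames=syn["n_frames"],
            noise_sd=syn["noise_sd"], seed=cfg.seed,
            twist_center=syn["twist_center_wt"], group="wt")
        mut = synthetic.gen_trajectory(
            structure, twist_range=syn["twist_range"],
            bend_range=syn["bend_range"], n_frames=syn["n_frames"],
            noise_sd=syn["noise_sd"], seed=cfg.seed + 1,
            twist_center=syn["twist_center_mut"], group="mut")
        from .structure import TrajectoryEnsemble
        ens = TrajectoryEnsemble.concatenate([wt, mut])
    first_dom = split.domain_names()[0]
    fit_idx = ens.domain_indices(split, first_dom, kind="backbone")
    ens = pca.superpose_ensemble(ens, fit_idx)
    sel = ens.select_indices(kind="backbone")
    pc = pca.covariance_pca(ens, sel)
    _fmt(pd.DataFrame({
        "mode": np.arange(1, min(10, pc.n_modes) + 1),
        "eigenvalue_A2": pc.eigenvalues[:10],
        "variance_fraction": pc.variance_fractions[:10],
    }), os.path.join(out, "eigenvalues.tsv"))
    proj = pd.DataFrame(pc.projections[:, :3], columns=["pc1", "pc2", "pc3"])
    proj.insert(0, "group", pc.groups)
    _fmt(proj, os.path.join(out, "projections.tsv"))
    angles = pca.mode_angles(pc, 0, split)
    summary["pc1_variance_fraction"] = round(float(pc.variance_fractions[0]), 3)
    summary["pc1_twist_range_deg"] = round(angles.twist_range, 1)
    summary["pc1_bend_range_deg"] = round(angles.bend_range, 1)
    if len(set(pc.groups)) >= 2:
        report = pca.compare_ensembles(pc)
        _fmt(report.stats, os.path.join(out, "pc_group_stats.tsv"))
        summary["pc1_separation_sd"] = round(report.separations[1], 2)
        summary["pc1_overlap"] = round(report.overlaps[1], 3)
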