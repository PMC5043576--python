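# igtandem

Desk-scale structural and biophysical analysis of missense variants at
immunoglobulin (Ig) tandem interfaces of titin — the kind of variant where a
single residue exchange (e.g. a threonine to isoleucine in an I-band Ig
domain) destabilizes the fold and shifts the conformational preferences of
the domain chain without breaking its structure.

The package is for structural biologists and bioinformaticians who want the
computational side of such a characterization as reusable, tested building
blocks:

* **β-turn machinery** — detection of four-residue turns
  (Cα(i)–Cα(i+3) ≤ 7 Å), Hutchinson–Thornton type classification from the
  (φ,ψ) of i+1/i+2, four-tier Ramachandran region labels with a specific
  left-handed-helical (α_L) flag, and position-specific residue-propensity
  surveys over turn libraries.
* **Interface analysis** — geometric hydrogen bonds (distance + antecedent
  angle), cross-domain contacts, SASA-based side-chain burial
  (1 − SASA_complex/SASA_isolated, Shrake–Rupley on a deterministic
  golden-spiral lattice), interdomain torsion/bend/rise from principal
  domain axes, and formal-charge pole summaries.
* **Essential dynamics** — covariance PCA of superposed conformational
  ensembles, per-mode decomposition into interdomain twist and bend ranges,
  and wild-type-vs-mutant comparison of the sampled PC space (separation in
  pooled SD, histogram overlap).
* **NMR statistics** — chemical-shift perturbations
  Δδ_AV = √(Δδ_H² + (0.2·Δδ_N)²) with moderate/large classes at
  0.03/0.15 ppm, R2/R1 relaxation-ratio flagging against a trimmed
  mean + k·SD baseline, and the Karplus relation
  J = A·cos²(φ+Δ) + B·cos(φ+Δ) + C for ³J(C′_{k−1},Hα_k) comparisons.
* **Thermal melts** — two-state Boltzmann fits
  F(T) = pre(T) + [post(T) − pre(T)] / (1 + e^{(Tm−T)/k}) with linear
  baselines, Tm standard errors and ΔTm with propagated error.
* **Synthetic data** — generators for every input class (two-domain Ig-like
  tandems with planted twist/bend, rigid-body hinge trajectories, turn
  libraries, HSQC peak-list pairs, melt curves), each a pure function of
  (parameters, seed) with recorded ground truth, so every stage is testable
  without downloads.

Structures are read and written as PDB (via gemmi), trajectories as
multi-model PDB or plain-text XYZ frames, tables as TSV.

## Worked example

Fitting wild-type-like and mutant-like melt curves
(`python examples/01_melt_fitting.py`):

```
wt:  Tm = 62.24 +/- 0.05 C   (slope k = 1.54 C, derivative peak at 62.5 C)
mut:  Tm = 51.40 +/- 0.06 C   (slope k = 1.45 C, derivative peak at 51.5 C)
delta-Tm (mut - wt) = -10.84 +/- 0.08 C
```

The two curves were generated with true midpoints 62.3 °C and 51.4 °C plus
2% noise; the fits recover both within 0.1 °C, and the ΔTm ≈ −11 °C is the
signature of a strongly destabilized domain.

Comparing wild-type-like and mutant-like ensembles
(`python examples/05_ensemble_pca.py`):

```
variance captured: PC1: 96.2%  PC2: 2.5%  PC3: 0.0%
PC1 twist range: 59.8 deg   bend range: 0.0 deg
PC1 separation: 3.04 pooled SD   histogram overlap: 0.00
```

PC1 is the interdomain rotation; the two groups, planted with twist centers
±16°, separate by ~3 pooled SD with the wild-type-like group on the
positive (straighter) side.

The other examples cover CSP classification (`02`), turn surveys (`03`) and
interface geometry (`04`). A thin CLI bundles the same operations as
subcommands (`igtandem simulate|turnscan|geometry|hbonds|pca|csp|melt|report`);
`igtandem report` runs the whole chain and writes per-stage TSVs plus a
summary.

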