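# Methods

This note documents the models and conventions implemented in `igtandem`,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Geometric primitives

**Dihedrals.** Signed angles in degrees, IUPAC convention (checked against
Biopython's `calc_dihedral` in the test suite), range (−180°, 180°].
φ(i) = C(i−1)–N(i)–Cα(i)–C(i), ψ(i) = N(i)–Cα(i)–C(i)–N(i+1),
ω(i) = Cα(i−1)–C(i−1)–N(i)–Cα(i). A peptide C–N distance above 2.0 Å
(standard bond ≈ 1.33 Å, generous margin) is treated as a chain break and
the affected angles are reported as missing — never as silent zeros. ω is
computed for cis/trans reporting only.

**Superposition.** Least-squares rigid fit via
`scipy.spatial.transform.Rotation.align_vectors` (proper rotations only;
reflections excluded). Degenerate inputs (< 3 atoms, collinear clouds)
raise. RMSD is returned for the transformed mobile set.

**SASA.** Shrake–Rupley with a deterministic golden-spiral sphere lattice,
so results are reproducible bit-for-bit at fixed `n_points` (default 960;
the isolated-sphere error at 960 points is well under 1%). Probe radius
1.4 Å. Van der Waals radii are an editable element table
(`data/geometry.yaml`; defaults C 1.70, N 1.55, O 1.52, S 1.80 Å — the same
values mdtraj ships, which the tests exploit as an independent oracle).
Hydrogens are ignored everywhere in the package; deposited X-ray structures
lack them, and all criteria are heavy-atom criteria.

**Chain building.** `build_chain` converts (aa3, φ, ψ, ω) lists to
Cartesian backbones NeRF-style with idealized Engh/Huber-type bond lengths
and angles (config file). Poly-backbone only (N, Cα, C, O, optional Cβ with
L-chirality); the round trip `phi_psi(build_chain(spec))` closes to well
under 0.5°. Every synthetic fixture in the package is built this way.

## β-turns and the propensity survey

A turn is any four consecutive residues (no chain break) with
Cα(i)–Cα(i+3) ≤ 7.0 Å whose central pair is not part of a continuous
α-helix (both i+1 and i+2 within 30° of (−57°, −47°) *and* inside a run of
≥ 4 such residues). Both cutoffs are arguments. Types follow the
Hutchinson–Thornton windows: all four (φ,ψ) of i+1/i+2 within ±30° of the
canonical values — I (−60,−30; −90,0), I′ (60,30; 90,0), II (−60,120;
80,0), II′ (60,−120; −80,0), VIII (−60,−30; −120,120) — with a single
angle allowed ±45°; everything else is IV/unclassified; among multiple
matches the smallest total deviation wins (ties resolve in the canonical
table order). Type II necessarily places i+2 at positive φ, i.e. in the
left-handed helical (α_L) region that is sterically strained for any
residue with a side chain.

Ramachandran labels come from an editable four-tier box scheme
(`data/rama_regions.yaml`) in the spirit of the PROCHECK classification;
"generously allowed" tiers are the cores widened by ~45°. Because
"generously allowed" is scheme-dependent, the polygons ship as data, not
code. Independently of the tier, an α_L flag marks
φ ∈ (20°, 100°), ψ ∈ (−60°, 90°).

The survey counts residue identity per turn position. "Unique" turns are
deduplicated by (4-residue sequence, type) across the whole input —
the uniqueness criterion of large published turn surveys is not public, so
the policy is explicit and configurable (`dedup="sequence" | "none"`).
The Thr-specific check at i+2 (`thr_i2_hbond_check`) reports whether
OG1(i+2) hydrogen-bonds to the preceding main-chain carbonyl under the
package-wide geometric criterion; this bond is what lets threonine's
branched Cβ survive at a position that otherwise strongly favours glycine.

## Interface analysis

**Hydrogen bonds** are geometric: donor–acceptor heavy-atom distance
≤ 3.5 Å and antecedent–donor–acceptor angle ≥ 120° (skipped when the
antecedent atom is missing); no energy function. Donors: backbone N
(except Pro) and side-chain N/O of S, T, Y, K, R, N, Q, H, W; acceptors:
backbone/carboxyl/amide/hydroxyl oxygens and His ring nitrogens.
Backbone–backbone pairs less than two positions apart are excluded.

**Burial** of a side chain is 1 − SASA_sc(full tandem)/SASA_sc(isolated
own domain), clipped to [0, 1]. This is *not* the FoldX definition used
for the published 0.79 value; comparisons with that number are approximate
by construction (the optional deposited-structure script documents a
±0.15 tolerance). Glycine raises, with a pointer to pass a Cα-based
pseudo-side-chain explicitly.

**Interdomain geometry.** Each domain's long axis is the first principal
axis of its Cα cloud, oriented N→C; a near-spherical cloud (first/second
singular-value ratio < 1.2) raises. Torsion = dihedral(axis-A tip,
centroid A, centroid B, axis-B tip); bend = angle between axes; rise =
centroid separation. This is one convention among several in the
tandem-orientation literature — published torsion values derived from
other conventions may differ systematically even when trends agree, so
cross-tool comparisons should be qualitative. The tip dihedral is
undefined when a domain axis is exactly parallel to the inter-centroid
line; the synthetic generator tilts its domains a few degrees precisely to
keep the measurement conditioned (below).

**Pole charges.** Residues are projected onto the domain axis; the
`window` (default 10) residues at the low end form the N-pole cap, at the
high end the C-pole cap; formal charges D/E = −1, K/R = +1, H = 0 are
summed per cap.

## Ensemble PCA

Frames from all groups are concatenated *before* decomposition so
wild-type and mutant share one basis, then Kabsch-fitted on a reference
selection (fitting on domain A's backbone isolates interdomain motion).
The mass-unweighted Cartesian covariance of the selected coordinates is
eigendecomposed; numerically this is done by economy SVD of the centered
frames × 3N matrix, which yields identical eigenpairs at a fraction of the
cost when frames ≪ 3N (the trace identity Σλ = total variance is asserted
in tests). Eigenvector signs are fixed deterministically (largest-magnitude
component positive); at most frames − 1 modes carry variance, and
requesting more warns and truncates.

**Mode twist/bend ranges.** The two extreme conformations of a mode are
taken at the 2.5th/97.5th percentiles of its projections (percentile
rather than min/max to damp outliers; configurable). Two constructions are
supported:

* `method="frames"` (default): the 3 trajectory frames nearest each
  extreme projection are coordinate-averaged and measured with the
  interdomain-geometry convention above. Averaging a few like-projection
  frames damps per-frame coordinate noise without biasing the extreme.
* `method="reconstruct"`: mean + projection × eigenvector, the textbook
  linear construction. A rotation traces an arc in coordinate space while
  the eigenvector is its chord, so this provably *shrinks* large rotation
  ranges (about 10% at ±34°) — the test suite asserts exactly this
  inequality. That shrinkage is why "frames" is the default.

Twist range = |Δtorsion| and bend range = |Δbend| between the two
extremes; a mode with no projection spread reports zero ranges.

**Group comparison** orients each mode so the first group's mean
projection is positive (making "group 1 more positive on PC1" a stable
convention), then reports per-group means/SDs, the difference of the first
two groups' means in pooled-SD units, and the overlap coefficient of their
normalized projection histograms.

## NMR statistics

Δδ_AV = √(Δδ_H² + (w_N·Δδ_N)²) with w_N = 0.2, the common ¹⁵N scaling —
the exact published weighting behind any given study is often cited to
secondary literature, so the weight is an explicit argument. Classes use
strict inequalities (moderate: 0.03 < Δδ_AV < 0.15 ppm; large:
Δδ_AV > 0.15 ppm) with values exactly on a threshold assigned to the lower
class; a 10⁻⁹ ppm epsilon guards that boundary rule against float rounding
of ppm arithmetic. Unmatched residues are "unassigned", never dropped
silently.

R2/R1 flagging hardens "above the average" to ratio > mean + k·SD
(default k = 1) with mean and SD computed on the 5–95 percentile core of
the ratios, so the exchange-broadened residues being flagged cannot
inflate their own baseline.

The Karplus relation is J = A·cos²(φ+Δ) + B·cos(φ+Δ) + C with
configurable coefficients; defaults (A, B, C) = (3.72, −2.18, 1.28) Hz,
Δ = 120°, a literature-style parameterization for ³J(C′_{k−1},Hα_k) whose
phase places positive-φ (α_L) residues on the large-J limb. Only curve-shape
properties (periodicity, evenness, extremum location, the positive-φ/large-J
correspondence) are asserted in tests; absolute coefficients are
instrument/calibration choices.

## Thermal melts

F(T) = (a₁+b₁T) + [(a₂+b₂T) − (a₁+b₁T)] / (1 + exp((Tm−T)/k)), fitted to
the raw points by bounded nonlinear least squares (no interpolation).
Initialization: Tm at the maximum of the Savitzky–Golay-smoothed |dF/dT|
(window 9, polyorder 2; smoothing is used *only* here), baselines from
linear fits of the outer ~15% of points. A curve whose smoothed amplitude
does not exceed 5× the residual-noise estimate raises `NoTransitionError`;
non-convergence or a non-finite Tm covariance raises with diagnostics. The
derivative-peak temperature is reported alongside the sigmoid Tm since
some instruments report the former. ΔTm = Tm_b − Tm_a with error
√(se_a² + se_b²).

## Synthetic generators: what they emulate, and what they don't

All generators are pure functions of (parameters, seed). The root seed is
expanded into named substreams (CRC32 of the stream name mixed into a
`SeedSequence`), so adding a generator never perturbs another's draws.
Ground truth is recorded in object metadata and can be written as a JSON
sidecar.

**Tandem** (`gen_ig_tandem`): each domain is an idealized three-strand
antiparallel β-meander built with `build_chain` (strands (−120°, 130°),
II′-type connecting turns, ±2° dihedral jitter), 90 residues by default —
the length of the NMR construct such studies use, and long enough that the
Cα principal axis is sharply conditioned. The long axis is tilted 1.5° off
the tandem axis: large enough to keep the tip-dihedral torsion
well-defined in the extended arrangement, small enough that a pure twist
leaks < 2° into the apparent bend (the leak is
2·arcsin(sin τ · sin(twist/2)) ≈ τ at 60° twist). Domain B is a rigid copy
rotated by the planted twist about the inter-centroid axis and bent about
a perpendicular hinge axis through the linker region, then placed so the
closest heavy-atom approach between domains is 3.5 Å (a van der Waals
contact, giving the tandem a genuine, limited set of interface contacts).
A two-residue linker (default "TL") sits at the hinge. Planted angles are
therefore recovered exactly by construction in the noiseless case.
Charged poles (3 Lys at each domain's N-terminus, 3 Glu at its C-terminus)
reproduce the (+, −) pole pattern of Ig tandems; disable with
`charged_poles=False`.

**Trajectories** (`gen_trajectory`): domain B oscillates rigidly about the
hinge; twist samples `center ± range/2` and bend `[0, range]` as sinusoids
in frame time at incommensurate frequencies (2 and 3 cycles, random
phases). Sinusoidal sampling is the natural kinematics of motion along a
hinge mode and makes the marginal distribution arcsine — mass concentrates
at the turning points, so the 2.5–97.5 percentile span of 50 frames sits
at ≈ 99.7% of the planted range (uniform sampling would truncate it to
95%, i.e. ~3.4° of a 68° rotation would be an artifact of the estimator,
not of the data). Isotropic Gaussian coordinate noise (default 0.1 Å)
stands in for thermal fluctuation. The base structure must be built with
bend = 0 so the twist axis passes through both centroids.

**Turn libraries**: per-position residue counts are realized by
largest-remainder rounding of the requested frequencies (so a planted 78%
is exactly 78/100), shuffled, with leftover mass spread uniformly over
unlisted residues; four-mer sequences are kept unique by bounded
in-position swaps (which preserve the counts) so a
uniqueness-deduplicating survey sees every planted turn. Turn dihedrals
are canonical ± 5° jitter inside strand flanks.

**Peak lists**: wild-type shifts are uniform random (δ_H 6.5–9.8 ppm,
δ_N 105–130 ppm, rounded to typical reporting precision); planted
perturbations displace δ_H by exactly the target Δδ_AV (optionally split
into δ_N by `n_fraction`, scaled by 1/w_N so the target is preserved);
noise, if any, is added to the mutant list after planting.

**Melt curves**: the Boltzmann model plus linear baselines plus Gaussian
noise whose SD is a fraction of the transition amplitude (0.02 = "2%
noise").

What passing the recovery tests shows: the analysis machinery measures
what was planted, at the stated tolerances, under Gaussian noise. What it
does not show: anything about force-field realism, solvent, correlated
experimental noise, peak overlap/assignment errors, or aggregation
artifacts in real melts — the generators emulate the structure of the
inputs, not their physics.

## Problem sizes

The recovery analyses run at desk scale by choice: 50-frame trajectories
of a 2 × 90-residue tandem (backbone PCA over ~2200 coordinates via
economy SVD), 100-turn libraries, 91-residue peak lists, 141-point melt
curves, and 200-curve Monte Carlo sweeps for the Tm-recovery rate. The
full test suite and the acceptance script each complete in well under a
minute on one CPU.

## Known limitations

* The torsion/bend convention is this package's definition; absolute
  values are not directly comparable to tools using other conventions.
* Burial is SASA-ratio based, not an energy-model burial; published
  FoldX-derived fractions differ by construction.
* Linear mode reconstruction underestimates large rotations (documented
  above); use the default frame-based mode angles for rotational modes.
* H-bond detection is purely geometric and heavy-atom based; it neither
  places hydrogens nor scores energies.
* `build_chain` produces idealized poly-backbone geometry (no side chains
  beyond Cβ, no real sterics); it is a fixture builder, not a modelling
  tool.
* PDB parsing keeps the highest-occupancy altloc and drops hydrogens;
  mmCIF and crystallographic symmetry expansion are out of scope.
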