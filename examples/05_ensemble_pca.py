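"""Essential-dynamics PCA of wild-type-like vs mutant-like trajectories.

Generates two rigid-body hinge trajectories of the same tandem whose
twist distributions are offset (wild-type-like centered positive, mutant
negative), concatenates them, superposes on domain A, and runs covariance
PCA. PC1 captures the interdomain rotation; the per-group projection
statistics quantify how differently the two variants sample
conformational space.
"""

from igtandem import (compare_ensembles, covariance_pca, mode_angles,
                      superpose_ensemble)
from igtandem.structure import TrajectoryEnsemble
from igtandem.synthetic import gen_ig_tandem, gen_trajectory

base = gen_ig_tandem(seed=0)
split = base.metadata["split"]

wt = gen_trajectory(base, twist_range=30.0, twist_center=16.0, n_frames=50,
                    noise_sd=0.1, seed=1, group="wt")
mut = gen_trajectory(base, twist_range=30.0, twist_center=-16.0, n_frames=50,
                     noise_sd=0.1, seed=2, group="mut")
ens = TrajectoryEnsemble.concatenate([wt, mut])
ens = superpose_ensemble(ens, ens.domain_indices(split, "I10",
                                                 kind="backbone"))
pc = covariance_pca(ens, ens.select_indices(kind="backbone"))

print("variance captured: "
      + "  ".join(f"PC{m+1}: {f:.1%}"
                  for m, f in enumerate(pc.variance_fractions[:3])))
angles = mode_angles(pc, 0, split)
print(f"PC1 twist range: {angles.twist_range:.1f} deg   "
      f"bend range: {angles.bend_range:.1f} deg")

report = compare_ensembles(pc)
print(report.stats[report.stats["mode"] == 1].to_string(index=False))
print(f"PC1 separation: {report.separations[1]:.2f} pooled SD   "
      f"histogram overlap: {report.overlaps[1]:.2f}")
print("Wild-type-like frames project positive on PC1 (straighter tandem), "
      "mutant-like frames negative (more twisted) -- distinct conformational "
      "preferences from a single-residue change.")
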