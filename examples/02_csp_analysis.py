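"""Chemical-shift perturbation analysis of a wild-type/mutant HSQC pair.

Plants 6 large (0.20 ppm) and 10 moderate (0.08 ppm) perturbations in a
91-residue peak list, computes the weighted-average CSP
Ddelta_AV = sqrt(DdeltaH^2 + (0.2 DdeltaN)^2) and classifies residues at
the 0.03 / 0.15 ppm thresholds. Counts of this kind localize which part
of a fold a mutation perturbs without any structural change.
"""

from igtandem import classify_csp, csp
from igtandem.synthetic import gen_peaklists

planted = ([(r, 0.20) for r in (5, 12, 23, 40, 41, 60)]
           + [(r, 0.08) for r in (7, 15, 30, 33, 50, 55, 70, 78, 85, 90)])
wt, mut, truth = gen_peaklists(n_res=91, planted=planted, seed=0)

table = csp(wt, mut, w_n=0.2)
counts = classify_csp(table, moderate=0.03, large=0.15)

print(f"residues analysed : {len(table.data)}")
print(f"large  (> 0.15 ppm)      : {counts['large']}")
print(f"moderate (0.03-0.15 ppm) : {counts['moderate']}")
print(f"unperturbed              : {counts['none']}")
top = table.data.nlargest(3, "d_av")
print("largest perturbations:")
for _, row in top.iterrows():
    print(f"  residue {int(row.residue):3d}  Ddelta_AV = {row.d_av:.3f} ppm")
print("A small, clustered set of perturbed residues means the mutation "
      "distorts the fold only locally.")
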