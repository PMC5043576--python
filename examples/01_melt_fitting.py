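"""Fit two-state DSF melt curves and report the stability loss.

Generates wild-type-like and mutant-like melt profiles (Boltzmann sigmoid
plus 2% noise), fits each, and prints Tm with its standard error plus the
delta-Tm between them. A negative delta-Tm of ~11 C is the signature of a
strongly destabilizing single-residue exchange.
"""

from igtandem import delta_tm, fit_melting
from igtandem.synthetic import gen_melting_curve

wt_curve, _ = gen_melting_curve(tm=62.3, k=1.5, noise_frac=0.02, seed=1,
                                label="wt")
mut_curve, _ = gen_melting_curve(tm=51.4, k=1.5, noise_frac=0.02, seed=2,
                                 label="mut")

fit_wt = fit_melting(wt_curve)
fit_mut = fit_melting(mut_curve)
dtm, err = delta_tm(fit_wt, fit_mut)

for fit in (fit_wt, fit_mut):
    print(f"{fit.label}:  Tm = {fit.tm:.2f} +/- {fit.tm_stderr:.2f} C   "
          f"(slope k = {fit.k:.2f} C, derivative peak at "
          f"{fit.tm_derivative_peak:.1f} C)")
print(f"delta-Tm (mut - wt) = {dtm:.2f} +/- {err:.2f} C")
print("A delta-Tm this large matches the destabilization seen when whole "
      "secondary-structure elements are removed from an Ig fold.")
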