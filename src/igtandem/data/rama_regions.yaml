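# Ramachandran region polygons, four-tier scheme (core / allowed /
# generously allowed / disallowed) in the spirit of Morris et al. as used
# by PROCHECK. Regions are axis-aligned boxes [phi_min, phi_max, psi_min,
# psi_max] in degrees, checked in order; the first match wins and anything
# unmatched is "disallowed". "Generously allowed" tiers are the core
# regions widened by ~45 degrees. The scheme is editable because
# "generously allowed" is not a universal notion.

regions:
  - label: core alphaR
    boxes:
      - [-160, -45, -80, -5]
  - label: core beta
    boxes:
      - [-180, -45, 90, 180]
      - [-180, -45, -180, -150]
  - label: core alphaL
    boxes:
      - [40, 80, -10, 60]
  - label: allowed
    boxes:
      - [-180, -25, -100, 15]
      - [-180, -25, 70, 180]
      - [-180, -25, -180, -130]
      - [25, 100, -30, 80]
  - label: generously allowed
    boxes:
      - [-180, 0, -125, 40]
      - [-180, 0, 45, 180]
      - [-180, 0, -180, -105]
      - [20, 105, -60, 95]
      - [45, 180, 95, 180]

# The left-handed helical (alphaL) flag window: positive-phi conformations
# sterically strained for residues with a side chain (open intervals).
alphaL_flag:
  phi: [20, 100]
  psi: [-60, 90]
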