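# Default coarse-grain force-field parameter table.
#
# Martini-2.0-like magnitudes: sigma 0.47 nm for regular pairs, 0.43 nm
# for fine-mapped ring pairs, epsilon graded by polarity between 2.0 and
# 5.0 kJ/mol, and an enlarged sigma for the antifreeze (AF) bead against
# P4 water (the antifreeze mechanism).  These are documented defaults,
# not a verbatim copy of any published interaction matrix; substitute
# your own table here to reproduce a specific parameterization.
schema: 1
bead_types: [C1, Na, P3, P4, AF]
lj:
  # pair: {sigma: nm, eps: kJ/mol}; keys are unordered pairs
  C1-C1: {sigma: 0.47, eps: 3.5}
  C1-Na: {sigma: 0.47, eps: 2.7}
  C1-P3: {sigma: 0.47, eps: 2.3}
  C1-P4: {sigma: 0.47, eps: 2.0}
  C1-AF: {sigma: 0.47, eps: 2.0}
  Na-Na: {sigma: 0.47, eps: 4.0}
  Na-P3: {sigma: 0.47, eps: 4.0}
  Na-P4: {sigma: 0.47, eps: 4.5}
  Na-AF: {sigma: 0.47, eps: 4.5}
  P3-P3: {sigma: 0.47, eps: 4.5}
  P3-P4: {sigma: 0.47, eps: 5.0}
  P3-AF: {sigma: 0.47, eps: 5.0}
  P4-P4: {sigma: 0.47, eps: 5.0}
  P4-AF: {sigma: 0.57, eps: 5.0}   # enlarged AF bead disrupts P4 crystallization
  AF-AF: {sigma: 0.47, eps: 5.0}
ring:
  # applied when BOTH beads of a pair are fine-mapped ring beads
  sigma: 0.43
  eps_scale: 0.75
bonded:
  bond: {r0: 0.47, k: 1250.0}          # chain bonds, kJ/mol/nm^2
  angle: {theta0: 180.0, k: 25.0}      # cosine-harmonic chain angles, kJ/mol
  ring_bond: {r0: 0.32, k: 6000.0}     # stiff ring-edge bonds
  ring_constraint: {k: 2000.0}         # cross-ring distance restraints
water:
  af_per_p4_ratio: 0.1                 # one AF bead per ten P4 beads
  waters_per_p4: 4                     # one P4 bead = four real waters
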