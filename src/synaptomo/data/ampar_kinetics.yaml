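# Six-state AMPA receptor gating scheme for cleft Monte Carlo simulations.
#
# Topology: two sequential glutamate-binding steps (C0 -> C1 -> C2), a
# single open state reachable only from the doubly bound state
# (C2 <-> O), and long-lived desensitized states off each bound state
# (C1 <-> D1, C2 <-> D2).
#
# Rates transcribed from the hippocampal AMPAR gating model of
# Jonas, Major & Sakmann (J Physiol 1993) as reduced to this six-state
# topology for particle-based Monte Carlo studies of quantal
# transmission. Binding rates are per free site times the statistical
# factor (two sites free in C0). Units: glutamate-binding rates in
# M^-1 s^-1, all others in s^-1. Edit freely; every simulation result is
# defined relative to the scheme actually configured.
name: jonas93_sixstate
states: [C0, C1, C2, O, D1, D2]
transitions:
  - {from: C0, to: C1, rate: 9.18e6, order: glutamate-binding}  # 2 x 4.59e6
  - {from: C1, to: C0, rate: 4.26e3, order: unimolecular}
  - {from: C1, to: C2, rate: 2.84e7, order: glutamate-binding}
  - {from: C2, to: C1, rate: 3.26e3, order: unimolecular}
  - {from: C2, to: O,  rate: 4.24e3, order: unimolecular}
  - {from: O,  to: C2, rate: 9.00e2, order: unimolecular}
  - {from: C1, to: D1, rate: 2.89e3, order: unimolecular}
  - {from: D1, to: C1, rate: 9.20e1, order: unimolecular}
  - {from: C2, to: D2, rate: 1.72e2, order: unimolecular}
  - {from: D2, to: C2, rate: 7.27e-1, order: unimolecular}
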