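# Pairwise-energy force-field constants for the built-in simplified backend.
# Engineering defaults for a four-term decomposition (atr/rep/elec/sol);
# edit freely — every number the backend uses lives in this file.
elements:
  C: {lj_radius: 1.9,  lj_welldepth: 0.12, solv_dgfree: -0.5, solv_volume: 14.7, solv_lambda: 3.5}
  N: {lj_radius: 1.75, lj_welldepth: 0.16, solv_dgfree: 2.0,  solv_volume: 11.2, solv_lambda: 3.5}
  O: {lj_radius: 1.55, lj_welldepth: 0.16, solv_dgfree: 2.0,  solv_volume: 10.8, solv_lambda: 3.5}
  S: {lj_radius: 2.0,  lj_welldepth: 0.20, solv_dgfree: -1.0, solv_volume: 21.6, solv_lambda: 3.5}
  default: {lj_radius: 1.9, lj_welldepth: 0.12, solv_dgfree: 0.0, solv_volume: 14.7, solv_lambda: 3.5}
# Partial charges (elementary charge units). Backbone rules apply to every
# residue type; side-chain rules are keyed by one-letter amino-acid code.
charges:
  backbone: {N: 0.35, O: -0.55, C: 0.20}
  sidechain:
    D: {OD1: -0.5, OD2: -0.5}
    E: {OE1: -0.5, OE2: -0.5}
    K: {NZ: 1.0}
    R: {NH1: 0.5, NH2: 0.5}
    H: {ND1: 0.25, NE2: 0.25}
# Interaction envelope: terms switch linearly to zero between these radii (Å).
switch: {start: 5.5, end: 6.0}
# Distance-dependent dielectric eps(r) = dielectric_slope * max(r, dielectric_floor)
electrostatics: {coulomb_constant: 332.0, dielectric_slope: 10.0, dielectric_floor: 1.6}
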