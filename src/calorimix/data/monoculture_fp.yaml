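# F. prausnitzii monoculture: triphasic growth (1.00 / 0.21 / 0.09 h^-1); the
# final phase converts acetate to butyrate.
# Medium is the same synthetic YCFAM pool as the consortium fixture;
# the inoculum approximates the serial-passage fixed point (1% v/v of a dense preculture).
strains:
- name: FP
  mu_max: {fp_sugars: 1.0, fp_slow: 0.12, acetate: 0.09}
  K: {fp_sugars: 0.005, fp_slow: 0.005, acetate: 0.005}
  yield_X: {fp_sugars: 0.01, fp_slow: 0.01, acetate: 0.01}
  yield_P:
    fp_sugars: {butyrate: 0.8, formate: 0.5}
    fp_slow: {butyrate: 0.8, formate: 0.5}
    acetate: {butyrate: 0.8}
  heat_yield: 20000.0
  copy_number: 6
  lag_h: 0.25
substrates: {mucin_glycans: 16.0, peptides: 3.0, bt_poly: 30.0, fp_sugars: 1.0, fp_slow: 1.2,
  acetate: 6.0}
initial_biomass: {FP: 0.0009}
transfer_fraction: 0.01
ampoule_volume_L: 0.002
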