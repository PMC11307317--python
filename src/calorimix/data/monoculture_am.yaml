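# A. muciniphila monoculture: mucin specialist, single growth phase at 0.57 h^-1.
# Medium is the same synthetic YCFAM pool as the consortium fixture;
# the inoculum approximates the serial-passage fixed point (1% v/v of a dense preculture).
strains:
- name: AM
  mu_max: {mucin_glycans: 0.57}
  K: {mucin_glycans: 0.005}
  yield_X: {mucin_glycans: 0.016}
  yield_P:
    mucin_glycans: {acetate: 1.0, propionate: 0.5}
  heat_yield: 20000.0
  copy_number: 3
  lag_h: 0.25
substrates: {mucin_glycans: 16.0, peptides: 3.0, bt_poly: 30.0, fp_sugars: 1.0, fp_slow: 1.2,
  acetate: 6.0}
initial_biomass: {AM: 0.0026}
transfer_fraction: 0.01
ampoule_volume_L: 0.002
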