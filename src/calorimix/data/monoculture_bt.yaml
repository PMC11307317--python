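# B. thetaiotaomicron monoculture: triphasic growth (0.88 / 0.20 / 0.07 h^-1)
# from sequential depletion of peptides, mucin glycans and a slow polysaccharide.
# Medium is the same synthetic YCFAM pool as the consortium fixture;
# the inoculum approximates the serial-passage fixed point (1% v/v of a dense preculture).
strains:
- name: BT
  mu_max: {peptides: 0.88, mucin_glycans: 0.13, bt_poly: 0.07}
  K: {peptides: 0.005, mucin_glycans: 0.005, bt_poly: 0.005}
  yield_X: {peptides: 0.01, mucin_glycans: 0.01, bt_poly: 0.01}
  yield_P:
    peptides: {acetate: 1.0, propionate: 0.5, succinate: 0.3, isobutyrate: 0.1}
    mucin_glycans: {acetate: 1.0, propionate: 0.5}
    bt_poly: {acetate: 0.5, succinate: 0.2}
  heat_yield: 20000.0
  copy_number: 5
  lag_h: 0.25
substrates: {mucin_glycans: 16.0, peptides: 3.0, bt_poly: 30.0, fp_sugars: 1.0, fp_slow: 1.2,
  acetate: 6.0}
initial_biomass: {BT: 0.0043}
transfer_fraction: 0.01
ampoule_volume_L: 0.002
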