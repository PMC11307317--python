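# Three-strain gut consortium in a synthetic YCFAM-like medium.
# Phase growth rates (h^-1) follow the monoculture kinetics of
# A. muciniphila (0.57), B. thetaiotaomicron (0.88 / 0.20 / 0.07) and
# F. prausnitzii (1.00 / 0.21 / 0.09); in the additive capped-Monod model a
# later phase rate is the sum of the remaining substrate terms, so BT's
# mucin term is 0.13 (0.13 + 0.07 = 0.20) and FP's slow-sugar term is 0.12
# (0.12 + 0.09 = 0.21).  16S copy numbers are 3 / 5 / 6.
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
  - name: FP
    mu_max: {fp_sugars: 1.00, fp_slow: 0.12, acetate: 0.09}
    K: {fp_sugars: 0.005, fp_slow: 0.005, acetate: 0.005}
    yield_X: {fp_sugars: 0.01, fp_slow: 0.01, acetate: 0.01}
    yield_P:
      fp_sugars: {butyrate: 0.8, formate: 0.5}
      fp_slow: {butyrate: 0.8, formate: 0.5}
      acetate: {butyrate: 0.8}
    heat_yield: 20000.0
    copy_number: 6
    lag_h: 0.25
substrates:
  mucin_glycans: 16.0
  peptides: 3.0
  bt_poly: 30.0
  fp_sugars: 1.0
  fp_slow: 1.2
  acetate: 6.0
initial_biomass: {AM: 1.0e-3, BT: 1.0e-3, FP: 1.0e-3}
transfer_fraction: 0.01
ampoule_volume_L: 0.002
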