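# Product-feedback inhibition: beta-galactosidase is competitively inhibited
# by its own product galactose (K_i = 13.7 mM).  Gal0 is galactose added
# before the reaction; newly produced galactose is wired into the same
# inhibitor pool.
motif:
  name: product_feedback
  parameters:
    K_m: 0.167 mM
    k_cat: 2903 per_s
    K_i: 13.7 mM
    E0: 0.7 nM
    S0: 1.0 mM
    I0: 0 mM
    Gal0: 40 mM
simulate:
  t_end: 7200 s
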