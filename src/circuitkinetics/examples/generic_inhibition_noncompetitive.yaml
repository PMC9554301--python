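# Generalised enzyme-substrate-inhibitor binding block, noncompetitive case
# (independent sites: K_m2 = K_m, K_i2 = K_i).  Change inhibition_type to
# competitive / uncompetitive / mixed to simulate the other mechanisms with
# the same three constants.
motif:
  name: inhibition
  parameters:
    inhibition_type: noncompetitive
    K_m: 2 mM
    k_cat: 500 per_s
    K_i: 3 mM
    E0: 10 nM
    S0: 5 mM
    I0: 3 mM
simulate:
  t_end: 3600 s
analysis:
  t_end: 20 s
  S0_grid:
    - 0.5 mM
    - 0.75 mM
    - 1 mM
    - 1.5 mM
    - 2 mM
    - 3 mM
    - 4 mM
    - 6 mM
    - 8 mM
    - 12 mM
    - 16 mM
    - 20 mM
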