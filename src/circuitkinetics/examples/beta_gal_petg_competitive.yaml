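# Competitive inhibition of beta-galactosidase by PETG (10 uM): the
# Michaelis-Menten circuit plus an enzyme-inhibitor binding block whose
# resistor is R = 1/K_i.
motif:
  name: inhibition
  parameters:
    inhibition_type: competitive
    K_m: 0.167 mM
    k_cat: 2903 per_s
    K_i: 2.33 uM
    E0: 0.3 nM
    S0: 1.2 mM
    I0: 10 uM
simulate:
  t_end: 3600 s
analysis:
  t_end: 120 s
  S0_grid:
    - 0.05 mM
    - 0.1 mM
    - 0.2 mM
    - 0.4 mM
    - 0.8 mM
    - 1.6 mM
    - 3.2 mM
    - 5.0 mM
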