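# Beta-galactosidase hydrolysing ONPG: quasi-steady-state Michaelis-Menten
# circuit with experimentally measured constants.  The ES resistor is
# R = 1/K_m = 5988 ohm.
motif:
  name: mm_qssa
  parameters:
    K_m: 0.167 mM
    k_cat: 2903 per_s
    E0: 0.3 nM
    S0: 1.2 mM
simulate:
  t_end: 3600 s
  points: 500
analysis:
  t_end: 120 s
  S0_grid:
    - 0.05 mM
    - 0.08 mM
    - 0.12 mM
    - 0.18 mM
    - 0.27 mM
    - 0.41 mM
    - 0.62 mM
    - 0.93 mM
    - 1.4 mM
    - 2.2 mM
    - 3.3 mM
    - 5.0 mM
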