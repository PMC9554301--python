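# Lactate dehydrogenase oxidising lactate at fixed saturating NAD+,
# noncompetitively inhibited by oxamate.  The fast NAD+ binding step is
# neglected, so the reaction reduces to a single-substrate noncompetitive
# circuit over the initial (forward-dominated) phase.
motif:
  name: inhibition
  parameters:
    inhibition_type: noncompetitive
    K_m: 17.1 mM
    k_cat: 215.5 per_s
    K_i: 3.66 mM
    E0: 5.0 nM
    S0: 80 mM
    I0: 7.6 mM
simulate:
  t_end: 360 s
analysis:
  t_end: 60 s
  S0_grid:
    - 5 mM
    - 10 mM
    - 20 mM
    - 40 mM
    - 80 mM
    - 160 mM
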