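# Two-substrate reaction where the enzyme must bind A before B (ordered).
# The binding block is the generalised ternary-complex circuit with
# substrates A and B in the substrate and inhibitor roles; only the ternary
# complex EAB is catalytically productive.  order: random | A_first | B_first.
motif:
  name: two_substrate
  parameters:
    order: A_first
    KdA: 1 mM
    KdB: 2 mM
    k_cat: 500 per_s
    E0: 10 nM
    A0: 2 mM
    B0: 2 mM
simulate:
  t_end: 3600 s
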