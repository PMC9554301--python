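# Yeast alcohol dehydrogenase: five-step reversible ordered Bi-Bi mechanism
# (NAD+ binds before ethanol; acetaldehyde releases before NADH).  The ten
# literature rate constants were adjusted to the original assay conditions
# in supplementary material that is not reproduced here, so they are shipped
# as UNKNOWN placeholders: fill in measured values before simulating.
# Bimolecular constants (k1, k2, km4, km5) take per_M_s; the rest per_s.
motif:
  name: reversible_bibi
  parameters:
    k1: UNKNOWN
    km1: UNKNOWN
    k2: UNKNOWN
    km2: UNKNOWN
    k3: UNKNOWN
    km3: UNKNOWN
    k4: UNKNOWN
    km4: UNKNOWN
    k5: UNKNOWN
    km5: UNKNOWN
    E0: 3.9 nM
    NAD0: 4 mM
    S0: 10 mM
simulate:
  t_end: 600 s
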