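# Cell-free transcription-translation repressed by a TetR homodimer.  The
# DNA template acts as the "enzyme": T7 RNAP (substrate) and TetR
# (inhibitor) bind noncompetitively at separate sites; only free DNA-RNAP
# transcribes.  Each transcribing template sequesters 1 + k_TX*Lm/Cm
# polymerases and each translated mRNA sequesters 1 + k_TL*Lp/Cp ribosomes.
# The fitted kinetic constants live in supplementary material that is not
# reproduced here; they are shipped as UNKNOWN placeholders.
motif:
  name: txtl
  parameters:
    k_TX: UNKNOWN
    d: UNKNOWN
    k_TL: UNKNOWN
    k_mat: UNKNOWN
    Lm: UNKNOWN
    Lp: UNKNOWN
    Cm: UNKNOWN
    Cp: UNKNOWN
    K_RNAP: UNKNOWN
    K_TetR: UNKNOWN
    K_ribo: UNKNOWN
    DNA0: 6 nM
    RNAP0: UNKNOWN
    Ribo0: UNKNOWN
    TetR0: 0 nM
simulate:
  t_end: 4000 s
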