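# Representative genes of fibroblastic subpopulation C1 (ASC/FAP-like):
# C7, CFD, PTGDS, all three of which appear in the twelve-gene PDAC
# chemo-resistance signature. Synthetic transcription for worked
# examples and tests.
C7
CFD
PTGDS
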