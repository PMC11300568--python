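# Representative genes of fibroblastic subpopulation C0 (COL11A1+,
# myCAF-like) adjacent to the ASC/FAP-like cluster C1. Synthetic
# reconstruction for worked examples and tests.
COL11A1
POSTN
MMP11
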