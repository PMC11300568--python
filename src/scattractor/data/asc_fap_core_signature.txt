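# Core ASC/FAP stromal-progenitor co-expression signature:
# APOD, DCN, LUM typically accompanied by CFD, CXCL14, PTGDS, MGP,
# SERPINF1 and DPT.
APOD
DCN
LUM
CFD
CXCL14
PTGDS
MGP
SERPINF1
DPT
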