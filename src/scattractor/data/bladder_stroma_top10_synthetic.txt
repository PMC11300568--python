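# Top ten DEGs (ranked by average fold change) of the ASC/FAP-containing
# stromal cluster in bladder cancer. Synthetic reconstruction for worked
# examples and tests.
APOD
DCN
LUM
MGP
CFD
PTGDS
CXCL14
SERPINF1
DPT
GSN
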