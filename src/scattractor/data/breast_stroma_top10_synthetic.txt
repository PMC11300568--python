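# Top ten DEGs (ranked by average fold change) of the ASC/FAP-containing
# stromal cluster in breast cancer. Synthetic reconstruction for worked
# examples and tests.
APOD
CFD
DCN
LUM
CXCL14
MGP
PTGDS
DPT
SERPINF1
CLU
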