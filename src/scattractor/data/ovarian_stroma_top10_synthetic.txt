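# Top ten DEGs (ranked by average fold change) of the ASC/FAP-containing
# stromal cluster in ovarian cancer. Synthetic reconstruction for worked
# examples and tests.
DCN
LUM
APOD
CFD
MGP
CXCL14
PTGDS
SERPINF1
C7
SFRP2
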