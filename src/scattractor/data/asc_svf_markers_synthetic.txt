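# Top marker genes of the adipose stromal cell (ASC) cluster in the
# stromal vascular fraction of normal human adipose tissue (GSE129363).
# Synthetic reconstruction for worked examples and tests, not a verbatim
# transcription of the published figure; shares exactly ten genes with
# the skeletal-muscle FAP list.
APOD
DCN
LUM
CFD
CXCL14
PTGDS
MGP
SERPINF1
DPT
GSN
CLU
APOE
C3
IGF1
FBLN1
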