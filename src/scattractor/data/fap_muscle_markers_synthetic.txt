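# Top marker genes of the fibro-adipogenic progenitor (FAP) cluster in
# human skeletal muscle. Synthetic reconstruction for worked examples and
# tests, not a verbatim transcription of the published figure; shares
# exactly ten genes with the adipose ASC list.
DCN
APOD
LUM
GSN
CFD
MGP
PTGDS
SERPINF1
CXCL14
DPT
SMOC2
PCOLCE2
ABCA8
FBN1
C1S
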