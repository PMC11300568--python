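# Twelve-gene pancreatic ductal adenocarcinoma "chemo-resistance
# signature" (top DEGs of a stromal population enriched three-fold in
# chemo-resistant samples). Synthetic reconstruction for worked examples
# and tests; contains C7, CFD and PTGDS as documented.
C7
CFD
PTGDS
APOD
DCN
LUM
CXCL14
MGP
SFRP2
PLA2G2A
FBLN1
GSN
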