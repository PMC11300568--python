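# Representative genes of fibroblastic subpopulation C2, the true
# IL6-positive inflammatory CAF (iCAF) population. Synthetic
# transcription for worked examples and tests.
IL6
HAS1
CCL2
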