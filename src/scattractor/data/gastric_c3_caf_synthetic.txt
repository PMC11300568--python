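# Marker genes of cluster C3 (COL11A1+THBS2+INHBA+ CAF), adjacent to the
# ASC/FAP-like cluster C0, consistent with the ASC/FAP-to-CAF
# transition. Synthetic transcription for worked examples and tests.
COL11A1
THBS2
INHBA
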