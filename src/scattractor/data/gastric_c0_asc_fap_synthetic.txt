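# Marker genes of cluster C0 (APOD+DCN+LUM+ ASC/FAP-like) in a gastric
# cancer fibroblast analysis. Synthetic transcription for worked
# examples and tests.
APOD
DCN
LUM
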