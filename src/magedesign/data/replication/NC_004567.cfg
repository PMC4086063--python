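# Lactobacillus plantarum WCFS1
origin=1369..1545
terminus=1655121..1655148
topology=circular
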