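# Pantoea ananatis AJ13355
origin=3803155..3803586
terminus=1523700..1523727
topology=circular
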