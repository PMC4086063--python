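# Pseudomonas syringae pv. tomato str. DC3000
origin=1..338
terminus=3211773..3211800
topology=circular
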