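# Lactobacillus reuteri F275 (terminus estimated opposite the origin)
origin=1324..1498
terminus=1021118
topology=circular
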