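# Salmonella typhimurium LT2
origin=4083788..4084165
terminus=1629676..1629703
topology=circular
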