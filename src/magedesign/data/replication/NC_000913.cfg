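# Escherichia coli str. K-12 substr. MG1655
origin=3923767..3923998
terminus=1339769..1682272
topology=circular
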