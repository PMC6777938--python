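(Onychophora,((Parasteatoda,Centruroides),((Strigamia,Sigmoria),((Triops,Hyalella),((Holacanthella,Catajapyx),(Machilis,(Drosophila,Apis)))))));
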