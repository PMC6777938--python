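species	Hairless	SuH_CtBP	SuH_Gro	SCAP
Onychophora	0	1	1	?
Parasteatoda	0	1	0	1
Centruroides	0	1	1	1
Strigamia	0	1	1	1
Sigmoria	0	1	1	?
Triops	1	1	1	0
Hyalella	1	1	1	0
Holacanthella	1	1	1	0
Catajapyx	1	1	1	0
Machilis	1	1	1	0
Drosophila	1	0	0	0
Apis	1	0	0	0
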