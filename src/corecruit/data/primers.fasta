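>HISsmarSUH-f
CGCTGGATCCGCGGCCAGTATGAC
>HISsmarSUH-r
CCATGGTACCAGTTATGCGTGGTG
>HISsmarSUHctbpm-f
AACCACgCCGcaGcTGcGgCTAACAGCCATCGCGGTGAAGGCGGCCAC
>HISsmarSUHctbpm-r
GCTGTTAGcCgCAgCtgCGGcGTGGTTGTCGGCGAAGTGAGGGGTCAG
>HISmbeta-f
cgatggatccgaATGGTTCTGGAAATGGAGATGTCCAAG
>HISmbetatrunc-r
ccatggtaccagTCACATGGGGCCagaggtggagctggcctcgctgggcgc
>mbetaSmarSuH-r
ccatggtaccagTCACACTTTATCAGGTGGAGTGAGAGAACCCATGGGGCCagaggtggagctggcc
>mbetaSmarSuHmut-r
ccatggtaccagTCAggctgccgctgcggctgccgctgctgcCATGGGGCCagaggtggagctggcc
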