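>Smar_SuHex2-3_WT role=wild_type pair=Smar_SuHex2-3
CGCTGGATCCGCGGCCAGTATGACTACCCGCCGCCGTTAGCCAGCACATACAGCCGCGAGGCCGACCTGTGGAACGTGAACCTGGCCACCTACAGCAGCGCACCGACCACATGCACCGGTGCAACCCCGGCACCTAGCGTTACCGGTTTCTACGCCCAGGCCACCGGCAGCAACAGCGTTAGCCCGAGTAGCGTGAGCCTGACCACCCTGACCCCTCACTTCGCCGACAACCACCCGGTGGACCTGAGCAACAGCCATCGCGGTGAAGGCGGCCACCTGGATCTGGTGCGCTTCCAGAGCGACCGCGTGGATGCCTACAAGCACGCCAACGGCCTGAGCGTGCATATCCCGGACCACCACGCATAACTGGTACCATGG
>Smar_SuHex2-3_mut role=mutant pair=Smar_SuHex2-3
CGCTGGATCCGCGGCCAGTATGACTACCCGCCGCCGTTAGCCAGCACATACAGCCGCGAGGCCGACCTGTGGAACGTGAACCTGGCCACCTACAGCAGCGCACCGACCACATGCACCGGTGCAACCCCGGCACCTAGCGTTACCGGTTTCTACGCCCAGGCCACCGGCAGCAACAGCGTTAGCCCGAGTAGCGTGAGCCTGACCACCCTGACCCCTCACTTCGCCGACAACCACgCCGcaGcTGcGgCTAACAGCCATCGCGGTGAAGGCGGCCACCTGGATCTGGTGCGCTTCCAGAGCGACCGCGTGGATGCCTACAAGCACGCCAACGGCCTGAGCGTGCATATCCCGGACCACCACGCATAACTGGTACCATGG
>Dmel_Hairless192-389_WT role=wild_type pair=Dmel_Hairless192-389 range=192-389
CGATGGATCCGAGCAGTGGTTGCAGCAGCAGCTGGCACTGCCAAAATTGGTAAAGGCAGCAACAGCGGTGGCAGTTTTGATATGGGCCGCACACCGATCAGCACCCACGGCAACAATAGTTGGGGTGGCTATGGCGGCCGTTTACAGTTCTTTAAAGATGGCAAGTTTATTTTAGAACTGGCCCGCAGCAAAGATGGCGATAAAAGCGGCTGGGTGAGTGTGACCCGCAAAACCTTTCGCCCGCCGAGTGCAGCAACCAGCGCAACCGTGACCCCTACCAGTGCCGTGACCACCGCCTACCCGAAGAATGAAAACAGCACCTCTTTAAGCTTCAGCGACGACAATAGCAGCATTCAGAGCAGCCCGTGGCAGCGTGATCAGCCGTGGAAACAGAGTCGTCCGCGCCGTGGCATCAGCAAAGAACTGTCTTTATTTTTCCACCGCCCGCGCAATAGTACACTGGGTCGTGCAGCCTTACGTACCGCAGCCCGCAAACGTCGTCGTCCGCATGAACCGCTGACCACCAGCGAAGATCAGCAGCCGATCTTTGCCACCGCAATCAAAGCCGAGAACGGTGATGATACTTTAAAAGCCGAAGCAGCCGAATAACTGGTACCATGG
>Dmel_Hairless192-389_5Amut role=mutant pair=Dmel_Hairless192-389 range=192-389
CGATGGATCCGAGCCGTTGTGGCAGCAGCAGCTGGCACTGCCAAAATCGGCAAAGGCAGCAATAGCGGTGGTAGCTTTGACATGGGCCGCACCCCGATTAGCACCCATGGCAACAACAGCTGGGGTGGTTATGGTGGTCGTGCCCAAGCTTTTAAAGACGGCAAGTTCATCGCCGAAGCCGCACGCAGCAAAGATGGCGACAAAAGCGGTGCCGTGAGCGTGACCCGCAAAACCTTTCGTCCGCCGAGTGCAGCAACCAGCGCAACCGTTACCCCGACCAGCGCAGTTACCACCGCCTACCCGAAAAACGAAAACAGCACCTCTTTAAGCTTTAGCGACGACAACAGCAGCATTCAGAGCAGCCCGTGGCAGCGCGATCAGCCGTGGAAACAGAGCCGTCCTCGTCGCGGCATCAGCAAAGAGCTGTCTTTATTCTTTCATCGCCCGCGCAATAGCACTTTAGGTCGTGCAGCACTGCGCACAGCAGCACGTAAACGTCGTCGCCCGCATGAACCGCTGACCACCAGCGAAGACCAGCAGCCGATTTTTGCCACCGCAATCAAAGCCGAGAACGGCGATGATACTTTAAAAGCAGAAGCAGCCGAATAACTGGTACCATGG
>Ptep_SCAP233-432_WT role=wild_type pair=Ptep_SCAP233-432 range=233-432
CGATGGATCCGAACCGTGAATACCGAAGATCCGCCGAAGGATAGCATCAACTTTCTGGACCACAGCCGCGTGACCGATCCGTGTAGTGCCGCAAGCGAAACCAGCCTGCCGCAGGATGTGCCGGCAACAAGCACCGTGGGCAGCCTGAAATTTTTTCTGGGCGGTCGCCTGGTGCTGAAATTAAACGCCCAGCAGGATGGCGGCAGCGGCAATAAATGCCAGTGGGTGCAGAGCAACGATCTGCCGAAACATAGCAACCATAACAAAAAAGATAAACATAAGAAAAAATTTGCACCGTATAGCTATAGCAGCAGCGGCACTCAGAAACCGCTGAAGAAAGGCGACGATACCAGTGCCGTGCCGGACTGTGATCCGAGCGGCATCAAAAAGCCGCGCCTGAAAGAGTACGAGACCAGCGAGAATAGCGCCCTGGGTCTGCTGCTGTGCAGCAGCAGTTGGACCCCGCCGGTTGCAGATGGTCAGGAGAGCATTGACGTGGACGATACCAGCAGCAAAACCAGCGAGGGCTATATTAGCCCGATCCTGAGCAACAATAGCCGCACCAGCAAAATCGACACCATCAAGCACGATTTTGCCAGCAACCCGAACACCTAACTGGTACCATGG
>Ptep_SCAP233-432_5Amut role=mutant pair=Ptep_SCAP233-432 range=233-432
CGATGGATCCGAACCGTGAACACCGAAGACCCGCCGAAAGATAGCATCAACTTTTTAGACCATAGCCGCGTGACAGACCCGTGCAGTGCCGCAAGTGAAACCTCTTTACCGCAAGATGTGCCGGCAACCAGCACCGTGGGTAGCGCCAAAGCCTTTCTGGGCGGTCGTCTGGTGGCCAAAGCCAATGCCCAGCAAGATGGTGGTAGTGGTAACAAATGCCAAGCTGTGCAGAGCAACGATCTGCCGAAACACAGCAATCACAATAAGAAAGACAAACACAAGAAAAAATTTGCCCCGTATAGCTATAGCAGCAGCGGCACCCAGAAACCGCTGAAAAAAGGCGATGACACCAGCGCAGTGCCGGATTGCGATCCGAGCGGCATTAAGAAACCGCGTTTAAAGGAGTACGAGACCAGCGAAAACAGTGCTTTAGGTTTACTGCTGTGCAGCAGCAGTTGGACACCGCCGGTGGCCGATGGTCAAGAAAGTATCGATGTGGACGACACCAGCAGCAAAACCAGCGAAGGCTACATCAGCCCGATTCTGAGCAACAATAGCCGCACCAGCAAAATTGATACCATTAAACATGATTTTGCAAGCAATCCGAATACCTAACTGGTACCATGG
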