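species	ctbp_context	gro_context
Ecdyonurus_insignis	YPDNH[PVDLS]SPRPH	APMIP[GSLTPPDKMNGE]HPHHG
Calopteryx_splendens	YTDNH[PVDLS]SPRPP	HHMIP[GSLTPPDKMNGE]HPAMH
Atelura_formicaria	YPDNH[PVDLS]SPRPQ	PHMIP[GSLTPPDKMNGE]HPHHS
Machilis_hrabei	YPDNH[PVDLS]SPRPH	PHMLP[GSLTPPDKMNGE]HPHHG
Catajapyx_aquilonaris	STANN[PVDLS]SPRGS	APMIP[GSLTPPDKVNGE]HHSHH
Holacanthella_duospinosa	VPNSN[PVDLS]NPSPS	SNFVP[GSLSPPERMNGN]DPSLL
Pollicipes_pollicipes	YPDNH[PVDLS]SPRPE	GPLIA[GSLTPPDKLGAE]LGLHA
Hyalella_azteca	SLGHR[PVDLS]QAPSP	AAMLA[GSLTPPDKLNSD]PQQQQ
Eurytemora_affinis	SETSA[PVDLS]APRPN	YGMLP[GSLTPPDKLNGD]HCSPG
Triops_cancriformis	HPEAR[PVDLS]SSRLL	YHSSS[LTLTPPDKVNVD]GSNSQ
Argulus_siamensis	YPENN[PVDLS]NSRTG	SPMIP[GSLTPPDKMNGE]HHPGH
Strigamia_maritima	FADNH[PVDLS]NSHRG	SHMIA[GSLTPPDKVNGE]HGHQL
Sigmoria_latior_munda	TNENH[PVDLS]SSHRS	SHMIP[GSLTPPDKGNAE]HSHSH
Metaseiulus_occidentalis	GADRK[PLDMS]AAHRS	
Ixodes_scapularis	QAAGA[PVDMS]SHPAR	
Parasteatoda_tepidariorum_1	VIDSH[PVDLS]SPKPS	
Parasteatoda_tepidariorum_2	RYEGR[PVDLS]SPRPN	
Limulus_polyphemus_1	PYDGH[PVDLS]NQRPD	
Limulus_polyphemus_2	TYESH[PVDLS]NQRPD	
Centruroides_sculpturatus	GYESS[PVDLS]SHRSV	MQLIS[GSMTSHDKVNGD]QHSLG
Euperipatoides_kanangrensis	NSYDN[PVDLS]SHRSS	QQILP[GSLGPSDKVNGD]LVSLA
Naineris_dendritica	DPNGH[PVDLS]HSRHI	PHMIH[GSLTPPDRVNGE]PGSGL
Platynereis_dumerilii	MASEN[PVDLS]SRHVG	GNHFP[GTLTPPDKLNGD]HNAHH
Nephasoma_pellucidum	AGYET[PVDLS]SPRPC	SHLIP[GSLTPPDKINGE]GITTS
Owenia_sp	QPYEN[PVDLS]RRHIK	AHLIP[GSLTPPDKINGD]MVTMA
Octopus_bimaculoides	NGFDN[PMDLS]NGKVV	HLMPA[GSLTPPDKISGD]SISMA
Crassostrea_gigas	GGYEN[PMDLS]SNKPG	SHIVA[GSLTPPEKINGD]PGAMA
Lottia_gigantea	AGVEN[PVDLS]NGRIS	SHLFT[GSLTPPEKPNGD]LVPMS
Notospermus_geniculatus	VQYDN[PIDLS]NRLEG	NHMIP[GSLTPPDKVNGD]MVPLP
Malacobdella_grossa	LHYDN[PLDLT]NRLDE	GSGIA[GSMTPPDGGKGN]DLDLQ
Lingula_anatina	GGYEN[PMDLS]RRTEM	AHMIP[GNLTPPDKVNGE]MVPMA
Phoronis_australis	QHDNR[PMDLS]SRGQH	SHLIA[GSLTPPDKVNGD]VVSMA
Procotyla_fluviatilis	ETLFE[PLDLR]SPIGV	
Brachionus_koreanus	AKDET[PIDLS]SKKSK	
Xenoturbella_bocki	KRYSA[PLNLT]VHDKC	DVRVL[GRLTPPDKQHVN]NDVGA
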