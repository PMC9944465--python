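peptide_id	kinases
PGFRB_1002_1014	PDGFRB
MET_1227_1239	MET
RAF1_332_344	SRC
ERBB2_1241_1253	ERBB2
FGFR2_762_774	FGFR2
LCK_387_399	Lck
PDPK1_369_381	SRC,INSR
CBL_693_705	ABl1
FAK1_569_581	RET,SRC
PGFRB_771_783	PDGFRB
KSYK_518_530	SYK
PGFRB_768_780	PDGFRB
VGFR2_1168_1180	VEGFR2
VGFR2_1052_1064	VEGFR2
PLCG1_764_776	SYK
PAXI_111_123	PTK6
FES_706_718	FES
PGFRB_572_584	PDGFRB
CDK2_8_20	WEE1
VGFR2_989_1001	VEGFR2
PGFRB_1014_1028	PDGFRB
FER_707_719	FER
VGFR2_1046_1058	VEGFR2
INSR_992_1004	INSR
EGFR_1165_1177	EGFR
ERBB4_1277_1289	ERBB4
EGFR_1190_1202	EGFR
FGFR1_761_773	FGFR1
CRK_214_226	ABL1
VGFR3_1061_1073	SRC,FLT4
ANXA2_17_29	SRC
EGFR_1103_1115	EGFR
VGFR2_944_956	VEGFR2
MK14_173_185	MAP2K3,MAP2K4,MAP14,MAP2K6
EPHA4_589_601	EPHA4
MK01_180_192	MAP2K1,MAP2K2
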