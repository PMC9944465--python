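peptide_id	cluster
PGFRB_1002_1014	A
MET_1227_1239	A
RAF1_332_344	A
ERBB2_1241_1253	A
FGFR2_762_774	A
LCK_387_399	A
PDPK1_369_381	A
CBL_693_705	A
FAK1_569_581	A
PGFRB_771_783	A
KSYK_518_530	A
PGFRB_768_780	A
VGFR2_1168_1180	A
VGFR2_1052_1064	A
PLCG1_764_776	B
PAXI_111_123	B
FES_706_718	B
PGFRB_572_584	B
CDK2_8_20	B
VGFR2_989_1001	B
PGFRB_1014_1028	B
FER_707_719	B
VGFR2_1046_1058	C
INSR_992_1004	C
EGFR_1165_1177	C
ERBB4_1277_1289	C
EGFR_1190_1202	C
FGFR1_761_773	C
CRK_214_226	C
VGFR3_1061_1073	C
ANXA2_17_29	C
EGFR_1103_1115	C
VGFR2_944_956	C
MK14_173_185	C
EPHA4_589_601	C
MK01_180_192	C
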