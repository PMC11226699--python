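strain	condition	component	mean	sd	flag
PD-1	aerobic	Q8	33.4	1.4	
PD-1	aerobic	DMK8	21.8	1.4	
PD-1	aerobic	MK8	44.7	0.8	
PD-1	anaerobic	Q8	55.3	2.6	
PD-1	anaerobic	DMK8	17.7	2.8	
PD-1	anaerobic	MK8	26.9	0.2	
M_tenebrionis_KCTC72449	aerobic	Q8	70.3	2.9	
M_tenebrionis_KCTC72449	aerobic	DMK8	3.51	1.9	
M_tenebrionis_KCTC72449	aerobic	MK8	26.2	0.3	
M_tenebrionis_KCTC72449	anaerobic	Q8	57.9	2.5	
M_tenebrionis_KCTC72449	anaerobic	DMK8	13.4	2.2	
M_tenebrionis_KCTC72449	anaerobic	MK8	28.8	0.3	
E_rhapontici_KCTC22740	aerobic	Q8	75.4	3.2	
E_rhapontici_KCTC22740	aerobic	DMK8	6.39	2.7	
E_rhapontici_KCTC22740	aerobic	MK8	18.2	0.02	
E_rhapontici_KCTC22740	anaerobic	Q8	54.3	2.6	
E_rhapontici_KCTC22740	anaerobic	DMK8	5.38	3.6	
E_rhapontici_KCTC22740	anaerobic	MK8	40.3	0.3	
E_coli_MG1655	aerobic	Q8	18.1	0.8	
E_coli_MG1655	aerobic	DMK8	35.5	1.3	
E_coli_MG1655	aerobic	MK8	46.3	0.9	
E_coli_MG1655	anaerobic	Q8	17.3	0.7	
E_coli_MG1655	anaerobic	DMK8	42.7	1.4	
E_coli_MG1655	anaerobic	MK8	40.0	0.8	
S_Typhimurium_ATCC14028	aerobic	Q8	27.4	1.2	
S_Typhimurium_ATCC14028	aerobic	DMK8	22.1	1.5	
S_Typhimurium_ATCC14028	aerobic	MK8	50.5	0.9	
S_Typhimurium_ATCC14028	anaerobic	Q8	13.1	0.8	
S_Typhimurium_ATCC14028	anaerobic	DMK8	45.9	2.7	
S_Typhimurium_ATCC14028	anaerobic	MK8	41.0	0.6	
E_pyrinus_KCTC2590	aerobic	Q8	34.7	1.6	
E_pyrinus_KCTC2590	aerobic	DMK8	40.7	2.4	
E_pyrinus_KCTC2590	aerobic	MK8	24.5	0.3	
E_pyrinus_KCTC2590	anaerobic	Q8	30.1	1.4	
E_pyrinus_KCTC2590	anaerobic	DMK8	48.6	2.4	
E_pyrinus_KCTC2590	anaerobic	MK8	21.2	0.3	
E_teleogrylli_SCU-B244	aerobic	Q8	28.7	1.4	
E_teleogrylli_SCU-B244	aerobic	DMK8	59.7	2.9	
E_teleogrylli_SCU-B244	aerobic	MK8	11.6	0.04	
E_teleogrylli_SCU-B244	anaerobic	Q8	18.2	0.9	
E_teleogrylli_SCU-B244	anaerobic	DMK8	71.1	2.7	
E_teleogrylli_SCU-B244	anaerobic	MK8	10.7	0.08	
P_agglomerans_KACC15275	aerobic	Q8	100	0	
P_agglomerans_KACC15275	aerobic	DMK8			ND
P_agglomerans_KACC15275	aerobic	MK8			ND
P_agglomerans_KACC15275	anaerobic	Q8	100	0	
P_agglomerans_KACC15275	anaerobic	DMK8			ND
P_agglomerans_KACC15275	anaerobic	MK8			ND
P_ananatis_KACC22739	aerobic	Q8	100	0	
P_ananatis_KACC22739	aerobic	DMK8			ND
P_ananatis_KACC22739	aerobic	MK8			ND
P_ananatis_KACC22739	anaerobic	Q8	100	0	
P_ananatis_KACC22739	anaerobic	DMK8			ND
P_ananatis_KACC22739	anaerobic	MK8			ND
P_stewartii_KACC22737	aerobic	Q8	100	0	
P_stewartii_KACC22737	aerobic	DMK8			ND
P_stewartii_KACC22737	aerobic	MK8			ND
P_stewartii_KACC22737	anaerobic	Q8	100	0	
P_stewartii_KACC22737	anaerobic	DMK8			ND
P_stewartii_KACC22737	anaerobic	MK8			ND
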