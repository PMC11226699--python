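	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
A	0	27	98	120	36	89	198	240	23	65	41	26	72	18	250	409	371	0	24	208
R	27	0	32	0	23	246	1	9	240	64	15	464	90	14	103	154	26	201	8	24
N	98	32	0	905	0	103	148	139	535	77	34	318	1	14	42	495	229	23	95	15
D	120	0	905	0	0	134	1153	125	86	24	0	71	0	0	13	95	66	0	0	18
C	36	23	0	0	0	0	0	11	28	44	0	0	0	0	19	161	16	0	96	49
Q	89	246	103	134	0	0	716	28	606	18	73	153	114	0	153	56	53	0	0	35
E	198	1	148	1153	0	716	0	81	43	61	11	83	30	0	51	79	34	0	22	37
G	240	9	139	125	11	28	81	0	10	0	7	27	17	15	34	234	30	0	0	54
H	23	240	535	86	28	606	43	10	0	7	44	26	0	48	94	35	22	27	127	44
I	65	64	77	24	44	18	61	0	7	0	257	46	336	196	12	24	192	0	37	889
L	41	15	34	0	0	73	11	7	44	257	0	18	527	157	32	17	33	46	28	175
K	26	464	318	71	0	153	83	27	26	46	18	0	243	0	33	96	136	0	13	10
M	72	90	1	0	0	114	30	17	0	336	527	243	0	92	17	62	104	0	0	258
F	18	14	14	0	0	0	0	15	48	196	157	0	92	0	11	46	13	76	698	12
P	250	103	42	13	19	153	51	34	94	12	32	33	17	11	0	245	78	0	0	48
S	409	154	495	95	161	56	79	234	35	24	17	96	62	46	245	0	550	75	34	30
T	371	26	229	66	16	53	34	30	22	192	33	136	104	13	78	550	0	0	42	157
W	0	201	23	0	0	0	0	0	27	0	46	0	0	76	0	75	0	0	61	0
Y	24	8	95	0	96	0	22	0	127	37	28	13	0	698	0	34	42	61	0	28
V	208	24	15	18	49	35	37	54	44	889	175	10	258	12	48	30	157	0	28	0
pi	0.087126912873087131	0.040903959096040908	0.040431959568040438	0.046871953128046873	0.033473966526033475	0.038254961745038257	0.04952995047004953	0.088611911388088618	0.033617966382033626	0.036885963114036892	0.085356914643085369	0.08048191951808048	0.014752985247014754	0.039771960228039777	0.050679949320050689	0.069576930423069588	0.058541941458058543	0.010493989506010494	0.029915970084029919	0.064717935282064723
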