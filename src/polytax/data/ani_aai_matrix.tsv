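	PD-1	P_beijingensis	W_iniecta	W_arboricola	W_toletana	M_theicola	M_alhagi	M_calida	M_gaviniae	M_tenebrionis	E_oleae	E_billingiae	E_psidii	E_aphidicola	E_persicina
PD-1	100	81	79	79	79	79	79	79	79	78	76	77	76	77	77
P_beijingensis	79	100	82	81	81	78	78	79	78	77	77	79	76	78	78
W_iniecta	79	80	100	86	86	79	79	79	79	78	77	79	76	79	78
W_arboricola	79	80	83	100	95	78	79	79	79	78	77	79	76	78	78
W_toletana	79	80	83	91	100	78	79	79	78	77	77	79	76	78	78
M_theicola	79	79	79	79	80	100	93	89	88	86	76	77	75	76	76
M_alhagi	79	79	79	79	79	89	100	89	88	86	76	77	75	77	76
M_calida	79	79	79	79	80	84	84	100	94	88	76	77	75	77	76
M_gaviniae	80	79	79	80	80	84	83	90	100	87	76	77	75	77	76
M_tenebrionis	79	79	79	79	79	83	83	85	85	100	75	75	74	76	76
E_oleae	78	79	79	79	81	79	79	79	80	79	100	80	78	78	78
E_billingiae	79	79	80	80	80	79	79	79	79	79	80	100	80	80	79
E_psidii	79	79	79	79	79	78	79	79	78	78	79	80	100	77	78
E_aphidicola	79	79	80	80	80	79	79	80	80	80	80	81	79	100	86
E_persicina	78	79	80	79	79	79	79	79	79	79	79	80	79	83	100
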