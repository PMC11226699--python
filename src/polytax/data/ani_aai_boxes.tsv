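cluster	members
Winslowiella	P_beijingensis,W_iniecta,W_arboricola,W_toletana
Mixta	M_theicola,M_alhagi,M_calida,M_gaviniae,M_tenebrionis
Erwinia_ob	E_oleae,E_billingiae
Erwinia_ap	E_aphidicola,E_persicina
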