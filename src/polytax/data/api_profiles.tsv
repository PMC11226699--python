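test	PD-1_24h	PD-1_48h	P_beijingensis	ref2	ref3	ref4
citrate_utilization	V	ND	-	-	+	-
acetoin_production	-	ND	-	+	-	-
acid_glycerol	-	+	-	+	+	-
acid_erythritol	-	+	-	-	-	-
acid_d_arabinose	V	+	-	-	-	+
acid_l_xylose	-	-	-	+	+	-
acid_amygdalin	-	-	-	+	+	-
acid_arbutin	-	-	+	+	+	-
acid_esculin	-	-	+	+	+	+
acid_salicin	-	-	+	+	+	-
acid_d_cellobiose	-	-	-	+	+	-
acid_d_maltose	+	+	+	+	+	-
acid_d_lactose	-	-	-	+	+	-
acid_d_melibiose	+	+	+	+	+	-
acid_d_saccharose	-	-	+	+	+	-
acid_d_raffinose	-	-	-	+	-	-
acid_gentiobiose	+	V	+	+	-	-
acid_d_lyxose	-	-	+	-	-	-
acid_d_fucose	V	+	-	+	+	-
acid_d_arabitol	+	+	-	+	+	+
potassium_gluconate	-	-	-	V	-	+
potassium_2_keto_gluconate	-	-	-	-	-	+
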