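#genotrait-rules	v1
#name	expression	substrate_class
den_step1	(narG & narH & narI) | (napA & napB)
den_step2	nirS | nirK
den_step3	(norB & norC) | (norV & norW)
den_step4	nosZ
denitrification_to_nitrite	den_step1
denitrification_to_N2O	den_step2 & den_step3
denitrification_to_N2	den_step2 & den_step3 & den_step4
denitrification_complete	den_step1 & den_step2 & den_step3 & den_step4
uptake_glucose_abc	glcA & glcB	monosaccharides
uptake_fructose_pts	fruA	monosaccharides
uptake_xylose_mfs	xylE	monosaccharides
uptake_cellobiose_abc	cebE & cebF	oligosaccharides
uptake_maltose_abc	malE	oligosaccharides
osmolyte_trehalose	(otsA & otsB) | treS
oxidative_stress_defense	katE | sodA
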