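#genotrait-hierarchy	v1
#name	level1	level2	level3	strategy	value_type	binding	substrate_class
denitrification_to_nitrite	Resource use	Anaerobic respiration	Nitrate reduction to nitrite	resource use	binary	denitrification_to_nitrite
denitrification_to_N2O	Resource use	Anaerobic respiration	Nitrite reduction to N2O	resource use	binary	denitrification_to_N2O
denitrification_to_N2	Resource use	Anaerobic respiration	Denitrification to N2	resource use	binary	denitrification_to_N2
uptake_monosaccharides	Resource acquisition	Substrate uptake	Monosaccharide transport	resource acquisition	count	uptake_glucose_abc,uptake_fructose_pts,uptake_xylose_mfs	monosaccharides
uptake_oligosaccharides	Resource acquisition	Substrate uptake	Oligosaccharide transport	resource acquisition	count	uptake_cellobiose_abc,uptake_maltose_abc	oligosaccharides
osmolyte_synthesis	Stress tolerance	Osmotic stress	Trehalose synthesis	stress tolerance	binary	osmolyte_trehalose
ros_detoxification	Stress tolerance	Oxidative stress	ROS detoxification	stress tolerance	binary	oxidative_stress_defense
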