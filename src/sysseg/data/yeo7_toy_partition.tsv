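roi_id	network_label
Vis_1	Vis
Vis_2	Vis
Vis_3	Vis
Vis_4	Vis
SomMot_1	SomMot
SomMot_2	SomMot
SomMot_3	SomMot
SomMot_4	SomMot
DorsAttn_1	DorsAttn
DorsAttn_2	DorsAttn
DorsAttn_3	DorsAttn
DorsAttn_4	DorsAttn
SalVentAttn_1	SalVentAttn
SalVentAttn_2	SalVentAttn
SalVentAttn_3	SalVentAttn
SalVentAttn_4	SalVentAttn
Limbic_1	Limbic
Limbic_2	Limbic
Limbic_3	Limbic
Limbic_4	Limbic
Cont_1	Cont
Cont_2	Cont
Cont_3	Cont
Cont_4	Cont
Default_1	Default
Default_2	Default
Default_3	Default
Default_4	Default
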