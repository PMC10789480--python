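roi_id	network_label
VisCent_1	VisCent
VisCent_2	VisCent
VisCent_3	VisCent
VisPeri_1	VisPeri
VisPeri_2	VisPeri
VisPeri_3	VisPeri
SomMotA_1	SomMotA
SomMotA_2	SomMotA
SomMotA_3	SomMotA
SomMotB_1	SomMotB
SomMotB_2	SomMotB
SomMotB_3	SomMotB
DorsAttnA_1	DorsAttnA
DorsAttnA_2	DorsAttnA
DorsAttnA_3	DorsAttnA
DorsAttnB_1	DorsAttnB
DorsAttnB_2	DorsAttnB
DorsAttnB_3	DorsAttnB
SalVentAttnA_1	SalVentAttnA
SalVentAttnA_2	SalVentAttnA
SalVentAttnA_3	SalVentAttnA
SalVentAttnB_1	SalVentAttnB
SalVentAttnB_2	SalVentAttnB
SalVentAttnB_3	SalVentAttnB
LimbicOFC_1	LimbicOFC
LimbicOFC_2	LimbicOFC
LimbicOFC_3	LimbicOFC
LimbicTempPole_1	LimbicTempPole
LimbicTempPole_2	LimbicTempPole
LimbicTempPole_3	LimbicTempPole
ContA_1	ContA
ContA_2	ContA
ContA_3	ContA
ContB_1	ContB
ContB_2	ContB
ContB_3	ContB
ContC_1	ContC
ContC_2	ContC
ContC_3	ContC
DefaultA_1	DefaultA
DefaultA_2	DefaultA
DefaultA_3	DefaultA
DefaultB_1	DefaultB
DefaultB_2	DefaultB
DefaultB_3	DefaultB
DefaultC_1	DefaultC
DefaultC_2	DefaultC
DefaultC_3	DefaultC
TempPar_1	TempPar
TempPar_2	TempPar
TempPar_3	TempPar
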