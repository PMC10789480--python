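network_label	associative
VisCent	0
VisPeri	0
SomMotA	0
SomMotB	0
DorsAttnA	1
DorsAttnB	1
SalVentAttnA	1
SalVentAttnB	1
LimbicOFC	0
LimbicTempPole	0
ContA	1
ContB	1
ContC	1
DefaultA	1
DefaultB	1
DefaultC	1
TempPar	1
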