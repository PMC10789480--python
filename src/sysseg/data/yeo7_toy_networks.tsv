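network_label	associative
Vis	0
SomMot	0
DorsAttn	1
SalVentAttn	1
Limbic	0
Cont	1
Default	1
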