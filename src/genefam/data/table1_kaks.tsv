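pair	species	ka	ks
ZmSPL1-ZmSPL13	maize	0.135	0.164
ZmSPL5-ZmSPL25	maize	0.122	0.126
ZmSPL1-ZmSPL5	maize	0.394	0.395
ZmSPL1-ZmSPL25	maize	0.374	0.344
ZmSPL13-ZmSPL5	maize	0.346	0.651
ZmSPL13-ZmSPL25	maize	0.373	0.279
ZmSPL2-ZmSPL14	maize	0.100	0.063
ZmSPL3-ZmSPL18	maize	0.083	0.073
ZmSPL4-ZmSPL31	maize	0.145	0.093
ZmSPL6-ZmSPL11	maize	0.480	0.565
ZmSPL8-ZmSPL27	maize	0.114	0.122
ZmSPL9-ZmSPL29	maize	0.124	0.100
ZmSPL15-ZmSPL22	maize	0.173	0.385
ZmSPL22-ZmSPL24	maize	0.365	0.611
ZmSPL16-ZmSPL21	maize	0.101	0.085
ZmSPL17-ZmSPL20	maize	0.257	0.272
ZmSPL17-ZmSPL19	maize	0.553	0.526
ZmSPL20-ZmSPL19	maize	0.440	0.394
SbSPL2-SbSPL15	sorghum	0.228	0.467
SbSPL3-SbSPL6	sorghum	0.406	0.534
SbSPL3-SbSPL13	sorghum	0.206	0.474
SbSPL6-SbSPL13	sorghum	0.426	0.597
SbSPL18-SbSPL7	sorghum	0.265	0.611
SbSPL17-SbSPL9	sorghum	0.306	0.419
OsSPL2-OsSPL16	rice	0.380	0.519
OsSPL2-OsSPL18	rice	0.496	0.496
OsSPL3-OsSPL12	rice	0.487	0.524
OsSPL4-OsSPL11	rice	0.317	0.535
OsSPL5-OsSPL10	rice	0.338	0.412
OsSPL14-OsSPL17	rice	0.185	0.450
OsSPL16-OsSPL18	rice	0.292	0.461
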