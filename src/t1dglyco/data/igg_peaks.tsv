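peak_id	structure_label	galactose_count	sialic_count	bisecting	core_fucose	antennary_fucose	branching	high_mannose	note
GP1	FA1	0	0	0	1	0	low	0
GP2	A2	0	0	0	0	0	low	0
GP3	A2B	0	0	1	0	0	low	0
GP4	FA2	0	0	0	1	0	low	0
GP5	M5	0	0	0	0	0	low	1
GP6	FA2B	0	0	1	1	0	low	0
GP7	A2[6]G1	1	0	0	0	0	low	0
GP8	FA2[6]G1	1	0	0	1	0	low	0
GP9	FA2[3]G1	1	0	0	1	0	low	0
GP10	FA2[6]BG1	1	0	1	1	0	low	0
GP11	FA2[3]BG1	1	0	1	1	0	low	0
GP12	A2G2	2	0	0	0	0	low	0
GP13	A2BG2	2	0	1	0	0	low	0
GP14	FA2G2	2	0	0	1	0	low	0
GP15	FA2BG2	2	0	1	1	0	low	0
GP16	FA2G1S1	1	1	0	1	0	low	0
GP17	A2G2S1	2	1	0	0	0	low	0
GP18	FA2G2S1	2	1	0	1	0	low	0
GP19	FA2BG2S1	2	1	1	1	0	low	0
GP20	unknown	2	1	0	1	0	low	0	structure not determined; monosialylated-region features assumed
GP21	A2G2S2	2	2	0	0	0	low	0
GP22	A2BG2S2	2	2	1	0	0	low	0
GP23	FA2G2S2	2	2	0	1	0	low	0
GP24	FA2BG2S2	2	2	1	1	0	low	0
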