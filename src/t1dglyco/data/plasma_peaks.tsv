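peak_id	structure_label	galactose_count	sialic_count	bisecting	core_fucose	antennary_fucose	branching	high_mannose	note
GP1	FA2	0	0	0	1	0	low	0
GP2	FA2B	0	0	1	1	0	low	0
GP3	A2	0	0	0	0	0	low	0
GP4	FA2[6]G1	1	0	0	1	0	low	0
GP5	FA2[3]G1	1	0	0	1	0	low	0
GP6	FA2BG1	1	0	1	1	0	low	0
GP7	M6	0	0	0	0	0	low	1
GP8	A2G1	1	0	0	0	0	low	0
GP9	A2BG2	2	0	1	0	0	low	0
GP10	FA2G2	2	0	0	1	0	low	0
GP11	FA2BG2	2	0	1	1	0	low	0
GP12	M7	0	0	0	0	0	low	1	co-elutes with A2G2S1; dominant M7
GP13	A2G1S1	1	1	0	0	0	low	0
GP14	FA2G1S1	1	1	0	1	0	low	0
GP15	M8	0	0	0	0	0	low	1
GP16	A2G2S1	2	1	0	0	0	low	0
GP17	FA2BG2S1	2	1	1	1	0	low	0
GP18	FA2G2S1	2	1	0	1	0	low	0
GP19	M9	0	0	0	0	0	low	1
GP20	A2BG2S1	2	1	1	0	0	low	0
GP21	A2G2S2	2	2	0	0	0	low	0
GP22	FA2G2S2	2	2	0	1	0	low	0
GP23	FA2BG2S2	2	2	1	1	0	low	0
GP24	A3G3S1	3	1	0	0	0	high	0
GP25	A3G3S2	3	2	0	0	0	high	0
GP26	FA3G3S2	3	2	0	1	0	high	0
GP27	A3FG3S2	3	2	0	0	1	high	0
GP28	A3FG3S3	3	3	0	0	1	high	0
GP29	A3G3S3	3	3	0	0	0	high	0
GP30	A3G3S3	3	3	0	0	0	high	0	linkage isomer of GP29
GP31	FA3G3S3	3	3	0	1	0	high	0
GP32	A4G4S2	4	2	0	0	0	high	0
GP33	A4G4S3	4	3	0	0	0	high	0
GP34	FA4G4S3	4	3	0	1	0	high	0
GP35	A4FG4S3	4	3	0	0	1	high	0
GP36	A4G4S4	4	4	0	0	0	high	0
GP37	FA4G4S4	4	4	0	1	0	high	0
GP38	A4FG4S4	4	4	0	0	1	high	0
GP39	FA4FG4S4	4	4	0	1	1	high	0
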