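#gene	intron	variant	mutations	agez_before	agez_after	bps_before	bps_after	moved_closer	pyr_snv
ABCA4	6	1	c.769-784C>T	17	17	0.22	0.22	0	Yes
CCN6	2	1	c.49-763G>T	24	24	-0.15	-0.15	0	Yes
COL4A5	29	1	c.2395+1275C>G;c.2395+1292G>T	13	59	-1.28	-0.03	0	Yes
DMD	26	2	c.3603+820G>T	16	42	0.57	1.00	0	Yes
DMD	37	2	c.5325+1740_5325+1757del	17	17	-1.33	-0.06	1	NA
F8	13	2a	c.2113+461_2113+473del	74	61	0.83	0.83	1	NA
F8	18	2b	c.5999-798G>A	8	65	0.23	0.23	0	No
KRIT1	6	1	c.262+132_262+133del	9	88	0.14	0.14	0	NA
NF1	8	3	c.889-941G>T	8	21	-0.73	-0.73	0	Yes
NF2	5	1	c.516+232G>A	15	40	0.06	3.37	0	No
PAH	11	1	c.1199+502A>T	34	34	-1.64	-0.16	0	Yes
PKHD1	56	1	c.8798-459C>A	46	46	-1.42	1.95	0	No
PTS	2	1b	c.163+696del55	17	28	-1.83	1.01	1	NA
RPGRIP1	12	1a	c.1468-263G>C	10	24	-0.56	-0.56	0	Yes
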