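#gene	chrom	strand	intron	variant	start	end	size	mutation	site_label	me_a_before	me_a_after	me_d_before	me_d_after	rss_side	rss_coord	pe_source	rss_source
ATM	chr11	+	27	1b	108287410	108287521	112	c.3994-159A>G	A+32	7.71	8.12	8.49	8.49	none		LCLs	HBECs
ATM	chr11	+	27	1a	108287410	108287438	29	c.3994-193C>T	A-3			6.38	6.38	donor	108287438	LCLs;peripheral blood	HBECs
COL4A5	chrX	+	6	1	108570649	108570795	147	c.385-719G>A	A+46	5.25	5.25	7.51	7.51	donor	108570795	Hair bulb	HBECs
FBOX38	chr5	+	9	1	148411080	148411238	159	c.1093+532C>G	D+59	9.11	9.11	6.57	6.57	acceptor	148411080	Whole blood;lung tissue	HBECs
GLA	chrX	-	3	1	101401233	101401347	115	c.547+395G>C	D-5	5.10	5.10	7.82	7.82	acceptor	101401347	Whole blood	Cerebellum;K562 cells
MCCC2	chr5	+	10	1	71636104	71636167	64	c.1054G>A	e11 D-19	5.72	5.72	3.24	3.24	acceptor	71636104	Emetine-treated fibroblasts	HBECs
NPHP3	chr3	-	3	1	132717955	132718117	163	c.671-996C>G	D+50	6.50	6.50	0.56	0.56	donor	132717955	Leukocytes	HBECs
OCRL	chrX	+	4	1	129553236	129553301	66	c.239-4023A>G	D+1	8.18	8.18	2.68	10.86	acceptor	129553236	Skin fibroblasts	PA1 cells
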