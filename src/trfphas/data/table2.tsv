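phasirna_id	c1d_rpm	a1d_rpm	family	n_target_genes	n_transcripts	n_up	n_down	n_unchanged	footnote
1_541_136(+)	41.03	24.16	NBS-LRR	2	2	1	0	1
1_541_136(+)	41.03	24.16	STK	2	6	3	2	1	d
1_541_178(+)	539.81	439.36	RLK	1	1	0	0	1
6_1497_500(-)	1628.21	1188.46	NBS-LRR	1	4	1	0	3
6_1497_500(-)	1628.21	1188.46	STK	1	1	1	0	0
6_1497_500(-)	1628.21	1188.46	RLK	3	7	5	1	1
6_1500_369(-)	441.61	350.39	RLK	1	1	0	0	1
11_1518_166(+)	1368.32	291.07	AP2/ERF	1	1	1	0	0
11_1518_166(+)	1368.32	291.07	bHLH	1	2	1	0	1
11_1518_166(+)	1368.32	291.07	GRAS	1	2	0	0	2
11_1518_166(+)	1368.32	291.07	WRKY	2	3	3	0	0
11_1518_166(+)	1368.32	291.07	STK	7	12	5	3	4	D
11_1518_166(+)	1368.32	291.07	RLK	16	27	12	2	13	E
11_1518_229(+)	72.79	37.35	AP2/ERF	3	2	2	0	0
11_1518_229(+)	72.79	37.35	ERF	1
11_1518_229(+)	72.79	37.35	MYB	3	5	1	0	4
11_1518_229(+)	72.79	37.35	NAC	2	1	0	0	1
11_1518_229(+)	72.79	37.35	NBS-LRR	1	1	1	0	0
11_1518_229(+)	72.79	37.35	STK	3	4	3	0	1
11_1518_229(+)	72.79	37.35	RLK	1	2	1	1	0
11_1518_250(+)	2035.14	1398.8	ARF	1	1	1	0	0
1_1364_205(-)	103.08	239.45	ARF	1	1	0	0	1	a
1_1364_205(-)	103.08	239.45	STK	3	4	2	0	2	b
1_1364_226(-)	25.4	64.8	ARF	1	1	0	0	1	a
1_1364_226(-)	25.4	64.8	STK	3	4	2	0	2	b
1_1364_249(+)	74.25	174.64	MYB	1					c
9_1750_102(+)	91.35	139.5	NBS-LRR	1	2	1	1	0
9_1750_102(+)	91.35	139.5	RLK	1	1	0	0	1
10_1305_229(+)	70.83	118.08	MYB	1					c
10_1305_418(+)	32.73	49.98	STK	1	2	1	1	0	d
11_131_361(+)	42.99	63.16	NBS-LRR	6	9	4	2	3
11_131_361(+)	42.99	63.16	STK	4	9	4	2	3	d
11_131_361(+)	42.99	63.16	RLK	2	2	0	0	2	e
11_2273_1539(+)	20.52	33.5	NBS-LRR	2	3	1	1	1
11_2273_1539(+)	20.52	33.5	RLK	1	1	1	0	0
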