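trait	group	qtl	left_marker	left_cM	right_marker	right_cM	vg_vp_pct	peak_lod	methods
L	3	qSCL3.1	C34-3876888	43.75	C34-3707103	47.09	6.58,28.19	8.84,15.00,8.11	GCIM,ICIM,CIM
L	9	qSCL9.1	C3-4785376	9.17	C3-5518941	20.40	24.61	13.82,23.35	IM,CIM
L	9	qSCL9.2	C3-5518941	20.40	C3-5518941	21.23	6.65	9.38	GCIM
L	9	qSCL9.3	C3-5518941	21.23	C_2_3-7327811	27.07	39.42,41.53,20.57	38.07,19.86,24.11,39.44	GCIM,ICIM,IM,CIM
L	9	qSCL9.4	C_2_3-7239571	28.73	C_2_3-6815285	30.40	19.39	19.36,24.82	IM,CIM
a	5	qSCa5.1	C_2_7-2469423	20.44	C_2_7-2494612	22.11	7.00,14.80	7.20,7.49,6.88	GCIM,ICIM,CIM
a	6	qSCa6.1	C4-7225533	78.80	U0167-32152	84.23	7.99,11.92	6.44,6.54,7.01	GCIM,ICIM,CIM
a	9	qSCa9.1	C3-5590000	21.23	C_2_3-7327811	27.07	13.38,31.97,24.42	16.60,15.19,17.95,18.45	GCIM,ICIM,IM,CIM
a	9	qSCa9.2	C_2_3-7239571	28.73	C_2_3-6815285	30.40	24.59	15.91,16.08	IM,CIM
b	3	qSCb3.1	C34-3876888	43.75	C34-4228322	44.17	14.80	7.49	ICIM
b	3	qSCb3.2	C34-4201909	44.59	C34-4201909	44.59	4.73	5.16	GCIM
b	5	qSCb5.1	C_2_7-2469423	20.44	C_2_7-2475883	21.27	11.96	6.08	ICIM
b	5	qSCb5.2	C_2_7-2476632	22.11	C_2_7-2476632	22.11	4.66	5.77	GCIM
b	9	qSCb9.1	C3-4785376	9.17	C3-5518941	20.40	22.85	10.47,29.43	IM,CIM
b	9	qSCb9.2	C3-5518941	20.40	C3-5518941	21.23	12.50	10.94	GCIM
b	9	qSCb9.3	C3-5518941	21.23	C_2_3-7327811	27.07	31.58,32.93,19.33	29.97,14.08,22.60,36.17	GCIM,ICIM,IM,CIM
b	9	qSCb9.4	C_2_3-7239571	28.73	C_2_3-6815285	30.40	18.00	17.76,22.42	IM,CIM
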