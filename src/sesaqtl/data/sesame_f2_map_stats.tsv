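LG	length_cM	n_bins	n_markers	avg_interval_cM	n_gaps	largest_gap_cM
1	110.96	1512	27577	0.66	2	7.56
2	106.05	1823	28880	0.87	3	12.97
3	105.61	981	20903	1.03	4	14.57
4	118.46	2234	37066	0.63	1	8.41
5	102.08	1339	18558	0.77	2	11.60
6	137.67	1794	26621	0.81	3	11.47
7	141.10	3090	49745	0.73	2	15.97
8	126.98	1930	32522	0.86	3	13.34
9	157.96	1705	24462	1.36	5	18.27
10	122.99	1383	29655	0.8	2	17.36
11	96.97	1379	25062	0.81	2	9.30
12	110.80	1835	30175	0.67	1	13.27
13	138.52	1370	29318	0.89	4	13.27
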