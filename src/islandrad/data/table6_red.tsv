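node	analysis	correlate	support_pct	islands	morphological_RED	n_diff	ecological_RED
9	consensus	inter	94	T-G	1.07	1	0.38
10	consensus	intra	100	T	1.07	1	0.88
11	consensus	intra	90	T	1.30	1	1.13
13	consensus	inter	100	T-P	1.20	1	0.67
15	consensus	intra	82	C	1.66	4	0.85
16	consensus	inter	100		0.87	2	0.65
17	consensus	inter	100		0.81	2	1.06
20	consensus	inter	100	C-G	1.00	1	0.92
22	consensus	inter	100	T-Md	0.87	2	0.90
23	consensus	intra	100	Md	1.80	3	1.00
24	consensus	intra	98	T	1.86	3	1.08
25	consensus	intra	84	T	0.00	0	0.40
26	consensus	inter	100	T-G	0.50	0	0.54
27	consensus	inter	98	T-C	0.33	0	0.52
28	consensus	inter	100		0.00	0	0.35
33	consensus	intra	94	G	1.58	3	0.82
45	consensus	intra	100	T	1.19	5	0.61
46	concatML	intra	100	T	1.19	5	0.63
46	ASTRAL	intra	100	T	1.69	4	0.67
46	dating	intra	100	T	1.47	5	0.76
47	concatML	intra	100	T	1.97	5	0.91
47	ASTRAL	intra	100	T	1.41	2	0.79
47	dating	intra	100	T	1.17	4	0.73
48	concatML	intra	100	T	1.25	3	1.35
48	ASTRAL	intra	100	T	1.25	3	1.35
48	dating	intra	100	T	1.90	4	0.56
49	concatML	intra	100	T	1.50	2	0.99
49	ASTRAL	intra	100	T	1.50	2	0.99
49	dating	intra	100	T	1.44	2	1.22
46-49	pooled	intra	100	T	1.48	3.42	0.91
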