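analysis	node_id	support_type	value
320-500_ASTRAL	9	BS	75
320-500_ASTRAL	10	BS	78
320-500_ASTRAL	11	BS	81
320-500_ASTRAL	13	BS	100
320-500_ASTRAL	15	BS	87
320-500_ASTRAL	16	BS	90
320-500_ASTRAL	17	BS	93
320-500_ASTRAL	20	BS	100
320-500_ASTRAL	22	BS	79
320-500_ASTRAL	23	BS	82
320-500_ASTRAL	24	BS	85
320-500_ASTRAL	25	BS	100
320-500_ASTRAL	26	BS	91
320-500_ASTRAL	27	BS	94
320-500_ASTRAL	28	BS	77
320-500_ASTRAL	30	BS	88
320-500_ASTRAL	33	BS	100
320-500_ASTRAL	35	BS	88
320-500_ASTRAL	45	BS	83
320-500_RAxML	9	BS	75
320-500_RAxML	10	BS	100
320-500_RAxML	11	BS	81
320-500_RAxML	12	BS	100
320-500_RAxML	13	BS	84
320-500_RAxML	15	BS	87
320-500_RAxML	16	BS	100
320-500_RAxML	17	BS	93
320-500_RAxML	20	BS	76
320-500_RAxML	22	BS	79
320-500_RAxML	23	BS	100
320-500_RAxML	24	BS	85
320-500_RAxML	25	BS	88
320-500_RAxML	26	BS	91
320-500_RAxML	27	BS	100
320-500_RAxML	28	BS	77
320-500_RAxML	30	BS	88
320-500_RAxML	33	BS	80
320-500_RAxML	35	BS	88
320-500_RAxML	45	BS	83
320-500_RAxML	46	BS	100
320-500_RAxML	47	BS	100
320-500_RAxML	48	BS	100
320-500_RAxML	49	BS	100
all_ASTRAL	9	BS	75
all_ASTRAL	10	BS	78
all_ASTRAL	11	BS	100
all_ASTRAL	12	BS	100
all_ASTRAL	13	BS	84
all_ASTRAL	15	BS	87
all_ASTRAL	16	BS	90
all_ASTRAL	17	BS	100
all_ASTRAL	20	BS	76
all_ASTRAL	22	BS	79
all_ASTRAL	23	BS	82
all_ASTRAL	24	BS	100
all_ASTRAL	25	BS	88
all_ASTRAL	26	BS	91
all_ASTRAL	27	BS	94
all_ASTRAL	28	BS	100
all_ASTRAL	30	BS	88
all_ASTRAL	33	BS	80
all_ASTRAL	35	BS	88
all_ASTRAL	45	BS	83
all_RAxML	9	BS	100
all_RAxML	10	BS	78
all_RAxML	11	BS	81
all_RAxML	12	BS	100
all_RAxML	13	BS	84
all_RAxML	15	BS	100
all_RAxML	16	BS	90
all_RAxML	17	BS	93
all_RAxML	20	BS	76
all_RAxML	22	BS	100
all_RAxML	23	BS	82
all_RAxML	24	BS	85
all_RAxML	25	BS	88
all_RAxML	26	BS	100
all_RAxML	27	BS	94
all_RAxML	28	BS	77
all_RAxML	30	BS	88
all_RAxML	33	BS	80
all_RAxML	35	BS	88
all_RAxML	45	BS	100
all_RAxML	46	BS	100
all_RAxML	47	BS	100
all_RAxML	48	BS	100
all_RAxML	49	BS	100
dating	9	PP	1.0
dating	10	PP	0.92
dating	11	PP	0.94
dating	12	PP	1.0
dating	13	PP	0.96
dating	15	PP	0.9
dating	16	PP	1.0
dating	17	PP	0.94
dating	20	PP	0.96
dating	22	PP	0.9
dating	23	PP	0.92
dating	24	PP	1.0
dating	25	PP	0.96
dating	26	PP	0.9
dating	27	PP	0.92
dating	28	PP	0.94
dating	30	PP	0.95
dating	33	PP	1.0
dating	35	PP	0.95
dating	45	PP	0.9
dating	46	PP	0.99
dating	47	PP	0.99
dating	48	PP	0.99
dating	49	PP	0.99
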