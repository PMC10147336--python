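taxon_a	taxon_b	islands	is_hybrid
A_aizoon	A_dodrantale	T	1
A_aizoon	A_urbicum_urbicum	T	0
A_ciliatum	A_haworthii	T	1
A_cuneatum	A_tabuliforme	T	0
A_castellopaivae	A_gomerense	G	1
A_castellopaivae	A_saundersii	G	0
A_diplocyclum	A_spathulatum	H+P+G	0
A_hierrense	A_valverdense	H	1
A_davidbramwellii	A_nobile	P	0
A_goochiae	A_nobile	P	1
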