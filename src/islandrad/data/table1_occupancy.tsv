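taxon	H	P	G	T	C	F	L	Mc	EA	Md	V
A_arboreum_arboreum	0	0	0	0	1	0	0	0	0	0	0
A_arboreum_holochrysum	1	1	1	1	0	0	0	0	0	0	0
A_balsamiferum	0	0	0	0	0	1	1	0	0	0	0
A_gorgoneum	0	0	0	0	0	0	0	0	0	0	1
A_korneliuslemsii	0	0	0	0	0	0	0	1	0	0	0
A_leucoblepharum	0	0	0	0	0	0	0	0	1	0	0
A_simsii	0	0	0	0	1	0	0	0	0	0	0
A_stuessyi	0	0	0	0	0	0	0	0	1	0	0
A_undulatum	0	0	0	0	1	0	0	0	0	0	0
A_canariense_canariense	0	0	0	1	0	0	0	0	0	0	0
A_canariense_christii	1	1	0	0	0	0	0	0	0	0	0
A_canariense_latifolium	0	0	1	0	0	0	0	0	0	0	0
A_canariense_virgineum	0	0	0	0	1	0	0	0	0	0	0
A_cuneatum	0	0	0	1	0	0	0	0	0	0	0
A_tabuliforme	0	0	0	1	0	0	0	0	0	0	0
A_smithii	0	0	0	1	0	0	0	0	0	0	0
A_spathulatum	1	1	1	1	1	0	0	0	0	0	0
A_goochiae	0	1	0	0	0	0	0	0	0	0	0
A_lindleyi_lindleyi	0	0	0	1	0	0	0	0	0	0	0
A_lindleyi_viscatum	0	0	1	0	0	0	0	0	0	0	0
A_aizoon	0	0	0	1	0	0	0	0	0	0	0
A_aureum	0	0	0	1	1	0	0	0	0	0	0
A_diplocyclum	1	1	1	0	0	0	0	0	0	0	0
A_dodrantale	0	0	0	1	0	0	0	0	0	0	0
A_appendiculatum	0	0	1	0	0	0	0	0	0	0	0
A_castellopaivae	0	0	1	0	0	0	0	0	0	0	0
A_ciliatum	0	0	0	1	0	0	0	0	0	0	0
A_davidbramwellii	0	1	0	0	0	0	0	0	0	0	0
A_decorum_alucense	0	0	1	0	0	0	0	0	0	0	0
A_decorum_decorum	0	0	1	1	0	0	0	0	0	0	0
A_escobarii	0	1	0	0	0	0	0	0	0	0	0
A_gomerense	0	0	1	0	0	0	0	0	0	0	0
A_haworthii	0	0	0	1	0	0	0	0	0	0	0
A_hierrense	1	0	0	0	0	0	0	0	0	0	0
A_lancerottense	0	0	0	0	0	0	1	0	0	0	0
A_mascaense	0	0	0	1	0	0	0	0	0	0	0
A_nobile	0	1	0	0	0	0	0	0	0	0	0
A_percarneum	0	0	0	0	1	0	0	0	0	0	0
A_pseudurbicum	0	0	0	1	0	0	0	0	0	0	0
A_urbicum_meridionale	0	0	0	1	0	0	0	0	0	0	0
A_urbicum_urbicum	0	0	0	1	0	0	0	0	0	0	0
A_valverdense	1	0	0	0	0	0	0	0	0	0	0
A_volkeri	0	0	0	1	0	0	0	0	0	0	0
A_glandulosum	0	0	0	0	0	0	0	0	0	1	0
A_saundersii	0	0	1	0	0	0	0	0	0	0	0
A_sedifolium	0	1	1	1	0	0	0	0	0	0	0
A_glutinosum	0	0	0	0	0	0	0	0	0	1	0
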