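island	cooccurrence_pct	hybridization_pct	habitation_age_myr
C	100.0	42.9	3.55
P	88.9	42.7	1.65
H	80.0	40.0	1.06
G	70.9	18.2	3.96
T	43.3	15.2	4.62
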