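model	LnL	d	e	j	AICc	AICc_wt
DEC	-197.4	0.051	0.180	0	399.0	1.2e-10
DEC+J	-180.9	0.026	0.042	0.049	368.4	5.0e-4
DIVALIKE	-195.8	0.054	0.140	0	395.9	5.6e-10
DIVALIKE+J	-184.0	0.030	0.043	0.041	374.6	2.4e-5
BAYAREALIKE	-207.8	0.055	0.520	0	419.9	3.4e-15
BAYAREALIKE+J	-173.4	0.021	0.044	0.050	353.3	1.0
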