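species	stage	mean_esd_mm	sd_esd_mm
mpacifica	C1	0.426	0.035
mpacifica	C2	0.517	0.045
mpacifica	C3	0.666	0.051
mpacifica	C4F	0.921	0.062
mpacifica	C4M	0.872	0.072
mpacifica	C5F	1.229	0.076
mpacifica	C5M	1.073	0.070
mpacifica	C6F	1.726	0.121
mpacifica	C6M	1.146	0.061
ebungii	C1	0.779	0.066
ebungii	C2	0.995	0.088
ebungii	C3	1.475	0.111
ebungii	C4F	2.089	0.116
ebungii	C4M	2.066	0.141
ebungii	C5F	2.865	0.222
ebungii	C5M	2.798	0.187
ebungii	C6F	3.827	0.276
ebungii	C6M	2.971	0.095
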