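set	criterion	sd3_beta_mach	sd3_beta_nar	sd3_beta_psych	sd3_r2	dd_beta_mach	dd_beta_nar	dd_beta_psych	dd_r2
psychopathy_empathy	BEES	-0.189	-0.070	-0.202	0.143	-0.064	0.052	-0.452	0.222
psychopathy_empathy	IRI F	0.026	-0.071	-0.023	0.006	0.219	0.077	-0.361	0.091
psychopathy_empathy	IRI EC	-0.155	-0.045	-0.230	0.131	-0.165	0.118	-0.383	0.203
psychopathy_empathy	IRI PT	-0.087	-0.006	-0.154	0.047	-0.137	0.068	-0.189	0.068
psychopathy_empathy	IRI PD	0.114	-0.283	-0.045	0.076	0.155	-0.076	-0.247	0.048
psychopathy_empathy	LSRP PP	0.331	0.135	0.371	0.467	0.382	0.066	0.331	0.451
psychopathy_empathy	LSRP SP	0.121	-0.260	0.401	0.194	0.277	-0.104	0.092	0.086
ffm	BFQ-SF E	-0.068	0.513	0.086	0.277	0.001	0.322	0.064	0.124
ffm	BFQ-SF A	-0.330	0.096	-0.238	0.219	-0.148	0.031	-0.324	0.170
ffm	BFQ-SF C	0.003	0.226	-0.228	0.064	-0.184	0.261	-0.114	0.062
ffm	BFQ-SF Em-St	-0.071	0.204	-0.212	0.065	-0.065	-0.111	0.039	0.020
ffm	BFQ-SF O	-0.027	0.144	-0.046	0.017	-0.046	0.166	-0.099	0.023
mental_health	SHS	-0.123	0.375	-0.020	0.120	-0.031	0.057	0.082	0.010
mental_health	BPNS Aut	-0.167	0.286	-0.008	0.075	-0.226	0.090	0.205	0.040
mental_health	BPNS Com	-0.128	0.431	-0.169	0.159	-0.188	0.247	0.012	0.044
mental_health	BPNS Rel	-0.186	0.389	-0.185	0.151	-0.237	0.169	-0.018	0.042
mental_health	STICSA	0.096	-0.241	0.180	0.069	0.115	0.021	-0.060	0.011
mental_health	TDI	0.085	-0.333	0.186	0.102	0.105	-0.069	-0.032	0.006
disinhibition	DvC Pros-total	0.064	0.198	-0.320	0.085	-0.280	0.309	-0.128	0.104
disinhibition	DvC Distr	0.146	-0.305	0.277	0.138	0.237	-0.142	0.055	0.050
disinhibition	DvC Manip	0.337	0.128	0.361	0.458	0.497	0.089	0.233	0.506
disinhibition	DvC Order	-0.029	0.083	-0.245	0.058	-0.097	0.001	-0.141	0.044
disinhibition	DvC Risk	-0.100	0.148	0.347	0.143	0.021	0.048	0.245	0.079
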