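set	criterion	sd3_mach	sd3_nar	sd3_psych	dd_mach	dd_nar	dd_psych
psychopathy_empathy	BEES	0.008	2.387	0.003	4.511	4.999	<0.001
psychopathy_empathy	IRI F	4.743	1.916	4.843	0.007	2.283	<0.001
psychopathy_empathy	IRI EC	0.074	4.673	<0.001	0.101	0.487	<0.001
psychopathy_empathy	IRI PT	1.594	5.941	0.107	0.471	2.832	0.014
psychopathy_empathy	IRI PD	0.630	<0.001	4.554	0.230	2.204	<0.001
psychopathy_empathy	LSRP PP	<0.001	0.015	<0.001	<0.001	3.538	<0.001
psychopathy_empathy	LSRP SP	0.402	<0.001	<0.001	<0.001	0.956	1.464
ffm	BFQ-SF E	3.401	<0.001	1.826	7.283	<0.001	3.359
ffm	BFQ-SF A	<0.001	0.810	<0.001	0.254	6.646	<0.001
ffm	BFQ-SF C	6.268	<0.001	0.001	0.059	<0.001	0.654
ffm	BFQ-SF Em-St	2.571	0.001	0.003	3.129	0.701	4.278
ffm	BFQ-SF O	4.845	0.087	3.873	4.241	0.058	1.097
mental_health	SHS	0.407	<0.001	6.702	4.719	3.147	1.794
mental_health	BPNS Aut	0.046	<0.001	6.398	0.006	1.494	0.005
mental_health	BPNS Com	0.304	<0.001	0.030	0.052	<0.001	5.794
mental_health	BPNS Rel	0.009	<0.001	0.011	0.003	0.047	5.594
mental_health	STICSA	1.240	<0.001	0.023	0.970	5.018	3.012
mental_health	TDI	1.842	<0.001	0.013	1.277	2.438	4.515
disinhibition	DvC Pros-total	3.153	0.002	<0.001	<0.001	<0.001	0.364
disinhibition	DvC Distr	0.132	<0.001	<0.001	0.003	0.197	3.607
disinhibition	DvC Manip	<0.001	0.032	<0.001	<0.001	1.056	<0.001
disinhibition	DvC Order	5.291	1.473	<0.001	1.679	5.915	0.212
disinhibition	DvC Risk	1.116	0.048	<0.001	6.111	4.289	<0.001
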