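family_id	individual_id	status	weighted_sum_score	prs	age_years
FMS01	FMS0119	affected	1.57	1.35	54
FMS01	FMS0124	affected	2.19	2.28	30
FMS01	FMS0132	affected	2.26	2.70	44
FMS01	FMS0157	affected	1.25	0.58	43
FMS01	FMS0121	unaffected	0.09	-1.61	56
FMS01	FMS0123	unaffected	-0.45	-0.94	33
FMS02	FMS0207	affected	1.21	1.02	31
FMS02	FMS0208	affected	2.12	1.55	34
FMS02	FMS0209	affected	0.80	1.09	25
FMS02	FMS0203	unaffected	1.64	2.02	68
FMS02	FMS0206	unaffected	0.78	0.26	59
FMS02	FMS0210	unaffected	1.48	1.38	39
FMS03	FMS0306	affected	-0.63	1.00	62
FMS03	FMS0307	affected	0.87	0.24	36
FMS03	FMS0318	affected	1.59	1.71	25
FMS03	FMS0305	unaffected	-0.16	-1.42	65
FMS03	FMS0308	unaffected	-1.18	-1.51	44
FMS03	FMS0309	unaffected	-1.21	-0.52	39
FMS04	FMS0411	affected	-0.28	0.67	58
FMS04	FMS0412	affected	-0.72	1.45	56
FMS04	FMS0429	affected	-1.10	-0.85	42
FMS04	FMS0430	affected	-0.61	-0.32	40
FMS04	FMS0431	unaffected	0.57	0.69	35
FMS04	FMS0432	unaffected	-0.40	-1.15	38
FMS05	FMS0503	affected	0.61	-1.20	56
FMS05	FMS0504	affected	1.32	-0.59	54
FMS05	FMS0522	affected	-0.17	-0.11	38
FMS05	FMS0501	unaffected	1.30	0.31	90
FMS05	FMS0506	unaffected	1.72	0.15	69
FMS05	FMS0511	unaffected	1.69	-0.35	52
FMS05	FMS0524	unaffected	-0.17	-0.73	43
FMS07	FMS0707	affected	0.62	1.19	44
FMS07	FMS0719	affected	-0.04	1.14	40
FMS07	FMS0721	affected	1.20	0.07	41
FMS07	FMS0704	unaffected	0.01	-0.59	69
FMS07	FMS0708	unaffected	-0.93	0.13	49
FMS07	FMS0709	unaffected	-1.16	0.05	47
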