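table	trait	outcome	kind	beta_h1	beta_h2	beta_h3	expected	expected_se	consistent
t2	height	gestational_days	maternal	0.038	0.17	-0.041	0.13	0.04	1
t2	height	gestational_days	fetal	0.038	0.17	-0.041	-0.089	0.041	1
t2	height	preterm	maternal	-0.027	-0.037	0.023	-0.044	0.0098	1
t2	height	preterm	fetal	-0.027	-0.037	0.023	0.016	0.0099	1
t2	height	birth_weight	maternal	20	6.3	14	6.3	1.4	1
t2	height	birth_weight	fetal	20	6.3	14	14	1.4	1
t2	height	birth_length	maternal	0.097	0.022	0.074	0.022	0.0076	1
t2	height	birth_length	fetal	0.097	0.022	0.074	0.074	0.0076	1
t2	bmi	gestational_days	maternal	-0.059	-0.11	0.027	-0.098	0.15	1
t2	bmi	gestational_days	fetal	-0.059	-0.11	0.027	0.043	0.15	1
t2	bmi	preterm	maternal	-0.065	0.015	0.049	-0.048	0.036	1
t2	bmi	preterm	fetal	-0.065	0.015	0.049	-0.018	0.036	0
t2	bmi	birth_weight	maternal	23	8.8	-6.5	19	5	1
t2	bmi	birth_weight	fetal	23	8.8	-6.5	4	5	1
t2	bmi	birth_length	maternal	0.066	0.079	0.027	0.06	0.028	1
t2	bmi	birth_length	fetal	0.066	0.079	0.027	0.0077	0.028	1
t2	bp	gestational_days	maternal	-0.22	-0.035	-0.016	-0.12	0.055	1
t2	bp	gestational_days	fetal	-0.22	-0.035	-0.016	-0.1	0.056	1
t2	bp	preterm	maternal	0.034	0.047	0.005	0.038	0.013	1
t2	bp	preterm	fetal	0.034	0.047	0.005	-0.0035	0.013	1
t2	bp	birth_weight	maternal	-6.8	-3.1	-5.9	-2	1.9	1
t2	bp	birth_weight	fetal	-6.8	-3.1	-5.9	-4.8	1.9	1
t2	bp	birth_length	maternal	-0.018	-0.018	-0.017	-0.0096	0.01	1
t2	bp	birth_length	fetal	-0.018	-0.018	-0.017	-0.0086	0.01	1
t2	fpg	gestational_days	maternal	-3.9	-3.2	2.7	-5	1.5	1
t2	fpg	gestational_days	fetal	-3.9	-3.2	2.7	0.99	1.5	1
t2	fpg	preterm	maternal	0.6	0.54	-0.38	0.77	0.37	1
t2	fpg	preterm	fetal	0.6	0.54	-0.38	-0.14	0.36	1
t2	fpg	birth_weight	maternal	13	270	-52	170	51	0
t2	fpg	birth_weight	fetal	13	270	-52	-150	50	0
t2	fpg	birth_length	maternal	-0.067	0.71	-0.13	0.37	0.28	0
t2	fpg	birth_length	fetal	-0.067	0.71	-0.13	-0.46	0.28	1
t2	t2d	gestational_days	maternal	0.013	0.05	0.83	-0.39	0.27	1
t2	t2d	gestational_days	fetal	0.013	0.05	0.83	0.4	0.27	1
t2	t2d	preterm	maternal	-0.0079	0.013	-0.11	0.058	0.063	1
t2	t2d	preterm	fetal	-0.0079	0.013	-0.11	-0.067	0.062	1
t2	t2d	birth_weight	maternal	-14	33	-28	24	8.9	1
t2	t2d	birth_weight	fetal	-14	33	-28	-39	8.8	1
t2	t2d	birth_length	maternal	-0.065	0.059	-0.033	0.015	0.049	1
t2	t2d	birth_length	fetal	-0.065	0.059	-0.033	-0.085	0.049	0
t3	birth_weight_score	gestational_days	maternal	-0.0056	0.001	-0.0099	0.0026	0.0023	1
t3	birth_weight_score	gestational_days	fetal	-0.0056	0.001	-0.0099	-0.0083	0.0023	1
t3	birth_weight_score	preterm	maternal	0.0024	-0.00058	0.0019	-5.8e-05	0.00055	1
t3	birth_weight_score	preterm	fetal	0.0024	-0.00058	0.0019	0.0025	0.00056	1
t3	birth_weight_score	birth_weight	maternal	0.79	-0.19	1.3	-0.33	0.076	1
t3	birth_weight_score	birth_weight	fetal	0.79	-0.19	1.3	1.1	0.075	1
t3	birth_weight_score	birth_length	maternal	0.0018	-0.00022	0.0031	-0.00073	0.00042	1
t3	birth_weight_score	birth_length	fetal	0.0018	-0.00022	0.0031	0.0025	0.00042	1
t4	birth_weight_score	sbp	maternal	-0.0026	0.00057	0.0043	-0.0032	0.0016	1
t4	birth_weight_score	sbp	fetal	-0.0026	0.00057	0.0043	0.00054	0.0016	1
t4	birth_weight_score	dbp	maternal	-0.00021	0.0006	0.0021	-0.00083	0.0011	1
t4	birth_weight_score	dbp	fetal	-0.00021	0.0006	0.0021	0.00065	0.0011	1
t4	birth_weight_score	fpg	maternal	-0.00011	-0.00025	8.9e-05	-0.00022	0.0002	1
t4	birth_weight_score	fpg	fetal	-0.00011	-0.00025	8.9e-05	0.00011	0.00019	1
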