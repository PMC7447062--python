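table	outcome	beta_h3_out	beta_h3_growth	sd	expected	expected_se	consistent
t3	gestational_days	-0.0099	1.3	426	-3.24	0.889	1
t3	preterm	0.0019	1.3	426	0.624	0.215	1
t3	birth_length	0.0031	1.3	426	1	0.172	1
t4	sbp	0.0043	1.3	426	1.41	0.621	1
t4	dbp	0.0021	1.3	426	0.69	0.426	1
t4	fpg	8.9e-05	1.3	426	0.029	0.0724	1
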