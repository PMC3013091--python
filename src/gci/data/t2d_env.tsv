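id	level	rel_risk	freq
BMI	<23	1.00	0.20
BMI	23-23.9	1.00	0.16
BMI	24-24.9	1.50	0.14
BMI	25-26.9	2.20	0.27
BMI	27-28.9	4.40	0.14
BMI	29-30.9	6.70	0.06
BMI	31-32.9	11.6	0.02
BMI	33-34.9	21.3	0.01
BMI	>=35	42.1	0.01
Smoking	Never Smoked	1.00	0.50
Smoking	Ex-Smoker	1.10	0.39
Smoking	<20 cigs/day	1.50	0.04
Smoking	>=20 cigs/day	1.70	0.07
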