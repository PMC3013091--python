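id	level	rel_risk	freq
Smoking	Never Smoked	1.00	0.545
Smoking	Ex-Smoker	1.70	0.245
Smoking	Current-Smoker	3.00	0.198
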