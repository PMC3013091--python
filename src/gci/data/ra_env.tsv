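id	level	rel_risk	freq
Smoking	Never Smoked	1.00	0.498
Smoking	Ex-Smoker	1.40	0.276
Smoking	Current-Smoker	1.30	0.227
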