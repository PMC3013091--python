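id	rr_hom	rr_het	freq_hom	freq_het
rs10118357	1.7278	1.3152	0.2712	0.5254
rs13207033	1.7559	1.3258	0.6667	0.3167
rs6457617	5.0847	2.3414	0.2167	0.5667
rs6679677	3.1672	1.6847	0.0000	0.2833
rs6920220	1.7023	1.1965	0.0000	0.3500
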