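id	rr_hom	rr_het	freq_hom	freq_het
rs153143	1.1586	1.0772	0.0170	0.1670
rs11634397	1.0961	1.0472	0.3280	0.5340
rs8042680	1.1112	1.0545	0.0330	0.3670
rs10012946	1.1464	1.0239	0.5000	0.4667
rs10811661	1.3008	1.1282	0.6667	0.2500
rs1801282	1.4128	1.2417	0.8667	0.1167
rs4402960	1.1602	1.1233	0.1167	0.3500
rs4506565	1.6133	1.2738	0.0847	0.3729
rs5215	1.1681	1.0935	0.1000	0.6167
rs8050136	1.3609	1.1176	0.1167	0.6667
rs10923931	1.1948	1.0947	0.0167	0.2000
rs4607103	1.1392	1.0681	0.6333	0.3500
rs7961581	1.1355	1.0664	0.0500	0.3667
rs864745	1.1530	1.0747	0.3158	0.4035
rs5015480	1.1456	1.0451	0.3167	0.4833
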