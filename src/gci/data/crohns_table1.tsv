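id	rr_hom	rr_het	freq_hom	freq_het
rs10883365	1.6154	1.1989	0.3000	0.4000
rs2066845	11.4381	3.0164	0.0000	0.0333
rs10489276	1.4130	1.1888	0.0333	0.3667
rs1894603	1.4608	1.2088	0.2542	0.4407
rs4871611	1.1654	1.0795	0.3667	0.5000
rs6679677	1.7116	1.3085	0.7167	0.2833
rs17234657	2.3052	1.5360	0.0667	0.2000
rs11175593	2.3532	1.5353	0.0000	0.0333
rs11584383	1.3899	1.1790	0.4333	0.4500
rs1456893	1.4371	1.1989	0.3667	0.5333
rs1736135	1.3898	1.1790	0.3000	0.5000
rs17582416	1.3432	1.1590	0.1667	0.4333
rs2872507	1.2527	1.1193	0.2167	0.5000
rs3764147	1.5580	1.2484	0.0847	0.3220
rs4263839	1.4852	1.2188	0.4167	0.4667
rs744166	1.3898	1.1790	0.3276	0.4483
rs762421	1.2751	1.1292	0.2500	0.4833
rs10210302	1.8433	1.1890	0.3000	0.5000
rs7746082	1.3663	1.1690	0.1017	0.4915
rs7927894	1.3432	1.1591	0.2333	0.3833
rs9858542	1.8316	1.0895	0.0333	0.4167
rs11805303	1.8525	1.3875	0.1000	0.3833
rs1000113	1.9102	1.5354	0.0000	0.0667
rs2066844	3.2543	1.9609	0.0000	0.2203
rs17221417	1.9118	1.2883	0.1000	0.5167
rs2542151	1.9997	1.2980	0.0500	0.2833
rs10761659	1.5461	1.2287	0.2333	0.6333
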