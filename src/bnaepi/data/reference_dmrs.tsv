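tissue	chrom	start	end	length	ml_72h	ml_0h	direction	context	gene_id	region	annotation
shoot	chrC07	18318906	18318977	72	0.12	0.43	hypo	CG	BnaC07g12690D	promoter	NRT1.6/NPF2.12
shoot	chrC07	18319032	18319214	183	0.03	0.10	hypo	CHH	BnaC07g12690D	promoter	NRT1.6/NPF2.12
shoot	chrC06	31598782	31598876	95	0.23	0.13	hyper	CHH	BnaC06g30920D	promoter	NRT1.7/NPF2.13
shoot	chrCnn	57013740	57013864	125	0.24	0.36	hyper	CHH	BnaCnng57240D	promoter	NRT1.11/NPF1.2
shoot	chrC04	32096889	32096944	56	0.34	0.10	hyper	CG	BnaC04g30250D	intron	Gln1;1
shoot	chrC04	32096889	32096944	56	0.34	0.10	hyper	CG	BnaC04g30250D	exon	Gln1;1
shoot	chrA05	17101604	17101779	176	0.14	0.05	hyper	CHH	BnaA05g22420D	promoter	Gln1;3
shoot	chrC06	2820212	2820332	121	0.05	0.01	hyper	CHH	BnaC06g02010D	promoter	Gln1;5
root	chrC08	19833588	19833747	160	0.14	0.23	hypo	CHH	BnaC08g15370D	promoter	NRT1.1/NPF6.3
root	chrA06	2701052	2701177	126	0.04	0.11	hypo	CHH	BnaA06g04560D	promoter	NRT2.1
root	chrC05	19042585	19042712	128	0.04	0.01	hyper	CHH	BnaC05g24580D	promoter	NRT1.5/NPF7.3
root	chrC08	33965938	33966022	85	0.17	0.42	hypo	CHG	BnaC08g36990D	promoter	NRT1.9/NPF2.9
root	chrCnn	14859936	14860033	98	0.10	0.04	hyper	CHH	BnaCnng15890D	promoter	NAXT1/NPF2.7
root	chrA02	11371814	11371951	138	0.09	0.18	hypo	CHH	BnaA02g18610D	intron	NIA1/NR
root	chrC04	32095812	32095894	83	0.34	0.06	hyper	CG	BnaC04g30250D	exon	Gln1;1/GS1;1
root	chrA07	13217084	13217222	139	0.05	0.01	hyper	CHH	BnaA07g15180D	promoter	CLCa
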