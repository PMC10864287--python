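Month	SY1 songs	SY1 INIs	SY2 songs	SY2 INIs	SY3 songs	SY3 INIs	SY4 songs	SY4 INIs	SY5 songs	SY5 INIs	Total songs	Total INIs
July			7	550	6	323	0	0	0	0	13	873
August			9	837	8	714	6	465	4	266	27	2282
September			7	895	11	1691	13	852	6	721	37	4159
October			4	578	10	1488	10	888	9	1308	33	4262
November			5	657	5	642	11	1070	10	1515	31	3884
December					10	1240	5	302	9	1094	24	2636
January	14	1681					11	930			25	2611
February	12	804	5	435	2	104	4	261			23	1604
March	9	480	4	274	7	516	5	296			25	1566
April	4	182	1	11	3	191	0	0			8	384
May	0	0	0	0	1	23	0	0			1	23
June	3	142	0	0	1	51	0	0			4	193
Totals	42	3289	42	4237	64	6983	65	5064	38	4904	251	24477
Days reviewed	90		145		157		169		92		653	
Hours reviewed	270		435		471		507		276		1959	
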