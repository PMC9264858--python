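# identifier: ON401054
# organism: Prosopocoilus castaneus
# genome_length: 17523
# circular: true
# complete: true
Gene	Strand	Start	End	Length	StartCodon	StopCodon	Intergenic
trnI	J	1	64	64	-	-	375
trnQ	N	440	508	69	-	-	-1
trnM	J	508	575	68	-	-	0
nad2	J	576	1589	1014	ATA	TAA	2
trnW	J	1592	1657	66	-	-	-8
trnC	N	1650	1710	61	-	-	0
trnY	N	1711	1775	65	-	-	1
cox1	J	1777	3307	1531	AAC	T	0
trnL2	J	3308	3372	65	-	-	0
cox2	J	3373	4060	688	ATA	T	0
trnK	J	4061	4130	70	-	-	0
trnD	J	4131	4193	63	-	-	0
atp8	J	4194	4349	156	ATT	TAA	-4
atp6	J	4346	5014	669	ATA	TAA	-1
cox3	J	5014	5797	784	ATG	T	0
trnG	J	5798	5861	64	-	-	0
nad3	J	5862	6213	352	ATG	T	0
trnA	J	6214	6278	65	-	-	-1
trnR	J	6278	6341	64	-	-	-1
trnN	J	6341	6404	64	-	-	0
trnS1	J	6405	6471	67	-	-	0
trnE	J	6472	6535	64	-	-	-2
trnF	N	6534	6598	65	-	-	0
nad5	N	6599	8315	1717	ATA	T	0
trnH	N	8316	8379	64	-	-	0
nad4	N	8380	9715	1336	ATG	T	-7
nad4l	N	9709	9996	288	ATG	TAA	2
trnT	J	9999	10061	63	-	-	0
trnP	N	10062	10127	66	-	-	5
nad6	J	10133	10630	498	ATG	TAA	-1
cytb	J	10630	11770	1141	ATG	T	0
trnS2	J	11771	11835	65	-	-	18
nad1	N	11854	12804	951	ATA	TAG	0
trnL1	N	12805	12868	64	-	-	0
rrnL	N	12869	14136	1268	-	-	0
trnV	N	14137	14205	69	-	-	-1
rrnS	N	14205	15014	810	-	-	0
control_region	-	15015	17523	2509	-	-	0
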