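# identifier: ON401055
# organism: Prosopocoilus laterotarsus
# genome_length: 17333
# circular: true
# complete: false
Gene	Strand	Start	End	Length	StartCodon	StopCodon	Intergenic
trnI	J	335	398	64	-	-	158
trnQ	N	557	625	69	-	-	-1
trnM	J	625	693	69	-	-	0
nad2	J	694	1707	1014	ATA	TAG	2
trnW	J	1710	1773	64	-	-	-8
trnC	N	1766	1825	60	-	-	0
trnY	N	1826	1889	64	-	-	1
cox1	J	1891	3421	1531	AAT	T	0
trnL2	J	3422	3485	64	-	-	0
cox2	J	3486	4170	685	ATC	T	0
trnK	J	4171	4240	70	-	-	0
trnD	J	4241	4303	63	-	-	0
atp8	J	4304	4459	156	ATT	TAA	-4
atp6	J	4456	5124	669	ATA	TAA	-1
cox3	J	5124	5907	784	ATG	T	0
trnG	J	5908	5970	63	-	-	0
nad3	J	5971	6322	352	ATA	T	0
trnA	J	6323	6387	65	-	-	-1
trnR	J	6387	6450	64	-	-	-1
trnN	J	6450	6513	64	-	-	0
trnS1	J	6514	6580	67	-	-	0
trnE	J	6581	6644	64	-	-	-2
trnF	N	6643	6706	64	-	-	0
nad5	N	6707	8423	1717	ATT	T	0
trnH	N	8424	8487	64	-	-	0
nad4	N	8488	9823	1336	ATG	T	-7
nad4l	N	9817	10104	288	ATG	TAA	2
trnT	J	10107	10171	65	-	-	-1
trnP	N	10171	10236	66	-	-	5
nad6	J	10242	10739	498	ATG	TAA	-1
cytb	J	10739	11879	1141	ATG	T	0
trnS2	J	11880	11944	65	-	-	18
nad1	N	11963	12913	951	ATA	TAG	0
trnL1	N	12914	12976	63	-	-	0
rrnL	N	12977	14242	1266	-	-	0
trnV	N	14243	14311	69	-	-	0
rrnS	N	14312	15116	805	-	-	NA
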