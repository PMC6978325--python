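genome	species	sex	gene	length_nt	start_codon	stop_codon
MN528026	Scrobicularia plana	F	cox1	1554	ATA	TAA
MN528026	Scrobicularia plana	F	nad4	1323	TTG	TAG
MN528026	Scrobicularia plana	F	trnH	65	.	.
MN528026	Scrobicularia plana	F	trnS2	64	.	.
MN528026	Scrobicularia plana	F	trnE	66	.	.
MN528026	Scrobicularia plana	F	nad3	348	ATA	TAA
MN528026	Scrobicularia plana	F	trnI	68	.	.
MN528026	Scrobicularia plana	F	trnK	64	.	.
MN528026	Scrobicularia plana	F	nad4L	291	ATT	TAA
MN528026	Scrobicularia plana	F	trnY	64	.	.
MN528026	Scrobicularia plana	F	trnT	63	.	.
MN528026	Scrobicularia plana	F	trnL1	66	.	.
MN528026	Scrobicularia plana	F	trnD	63	.	.
MN528026	Scrobicularia plana	F	trnL2	66	.	.
MN528026	Scrobicularia plana	F	nad1	924	GTG	TAG
MN528026	Scrobicularia plana	F	trnN	66	.	.
MN528026	Scrobicularia plana	F	nad5	1635	TTG	TAA
MN528026	Scrobicularia plana	F	trnR	67	.	.
MN528026	Scrobicularia plana	F	cob	1135	ATA	T**
MN528026	Scrobicularia plana	F	cox2	861	ATG	TAA
MN528026	Scrobicularia plana	F	trnV	69	.	.
MN528026	Scrobicularia plana	F	trnW	66	.	.
MN528026	Scrobicularia plana	F	trnG	68	.	.
MN528026	Scrobicularia plana	F	rrnS	896	.	.
MN528026	Scrobicularia plana	F	trnM	66	.	.
MN528026	Scrobicularia plana	F	atp8	129	ATT	TAG
MN528026	Scrobicularia plana	F	trnS1	71	.	.
MN528026	Scrobicularia plana	F	nad6	510	ATA	TAA
MN528026	Scrobicularia plana	F	rrnL	1269	.	.
MN528026	Scrobicularia plana	F	atp6	714	ATG	TAG
MN528026	Scrobicularia plana	F	cox3	882	ATA	TAG
MN528026	Scrobicularia plana	F	nad2	996	ATG	TAA
MN528026	Scrobicularia plana	F	trnP	66	.	.
MN528026	Scrobicularia plana	F	trnQ	67	.	.
MN528026	Scrobicularia plana	F	trnC	63	.	.
MN528026	Scrobicularia plana	F	trnA	65	.	.
MN528026	Scrobicularia plana	F	trnF	63	.	.
MN528027	Scrobicularia plana	M	cox1	1551	ATT	TAA
MN528027	Scrobicularia plana	M	nad4	1335	GTG	TAA
MN528027	Scrobicularia plana	M	trnH	63	.	.
MN528027	Scrobicularia plana	M	trnS2	65	.	.
MN528027	Scrobicularia plana	M	trnE	64	.	.
MN528027	Scrobicularia plana	M	nad3	348	ATA	TAA
MN528027	Scrobicularia plana	M	trnI	68	.	.
MN528027	Scrobicularia plana	M	trnK	66	.	.
MN528027	Scrobicularia plana	M	nad4L	285	ATT	TAG
MN528027	Scrobicularia plana	M	trnY	64	.	.
MN528027	Scrobicularia plana	M	trnT	64	.	.
MN528027	Scrobicularia plana	M	trnL1	65	.	.
MN528027	Scrobicularia plana	M	trnD	66	.	.
MN528027	Scrobicularia plana	M	trnL2	66	.	.
MN528027	Scrobicularia plana	M	nad1	927	ATT	TAG
MN528027	Scrobicularia plana	M	trnN	65	.	.
MN528027	Scrobicularia plana	M	nad5	1704	ATG	TAG
MN528027	Scrobicularia plana	M	trnR	65	.	.
MN528027	Scrobicularia plana	M	cob	1135	ATG	T**
MN528027	Scrobicularia plana	M	trnW	64	.	.
MN528027	Scrobicularia plana	M	rrnS	765	.	.
MN528027	Scrobicularia plana	M	trnV	66	.	.
MN528027	Scrobicularia plana	M	trnG	68	.	.
MN528027	Scrobicularia plana	M	cox2	5679	ATG	TAG
MN528027	Scrobicularia plana	M	trnM	67	.	.
MN528027	Scrobicularia plana	M	atp8	129	ATG	TAA
MN528027	Scrobicularia plana	M	trnS1	69	.	.
MN528027	Scrobicularia plana	M	nad6	510	ATT	TAG
MN528027	Scrobicularia plana	M	rrnL	1556	.	.
MN528027	Scrobicularia plana	M	atp6	705	ATT	TAA
MN528027	Scrobicularia plana	M	cox3	882	ATA	TAG
MN528027	Scrobicularia plana	M	nad2	1002	ATT	TAA
MN528027	Scrobicularia plana	M	trnP	67	.	.
MN528027	Scrobicularia plana	M	trnQ	67	.	.
MN528027	Scrobicularia plana	M	trnC	61	.	.
MN528027	Scrobicularia plana	M	trnA	65	.	.
MN528027	Scrobicularia plana	M	trnF	65	.	.
MN528028	Limecola balthica	F	cox1	1554	ATA	TAA
MN528028	Limecola balthica	F	nad4	1341	ATA	TAG
MN528028	Limecola balthica	F	trnH	64	.	.
MN528028	Limecola balthica	F	trnS2	65	.	.
MN528028	Limecola balthica	F	trnE	67	.	.
MN528028	Limecola balthica	F	nad3	348	ATA	TAG
MN528028	Limecola balthica	F	trnI	69	.	.
MN528028	Limecola balthica	F	trnK	65	.	.
MN528028	Limecola balthica	F	nad4L	291	GTG	TAA
MN528028	Limecola balthica	F	trnY	63	.	.
MN528028	Limecola balthica	F	trnT	64	.	.
MN528028	Limecola balthica	F	trnL1	66	.	.
MN528028	Limecola balthica	F	trnD	63	.	.
MN528028	Limecola balthica	F	trnL2	66	.	.
MN528028	Limecola balthica	F	nad1	924	ATG	TAG
MN528028	Limecola balthica	F	trnN	65	.	.
MN528028	Limecola balthica	F	nad5	1743	TTG	T**
MN528028	Limecola balthica	F	trnR	65	.	.
MN528028	Limecola balthica	F	cob	1140	ATT	TAA
MN528028	Limecola balthica	F	cox2	855	ATG	TAA
MN528028	Limecola balthica	F	trnV	66	.	.
MN528028	Limecola balthica	F	trnW	66	.	.
MN528028	Limecola balthica	F	trnG	66	.	.
MN528028	Limecola balthica	F	rrnS	880	.	.
MN528028	Limecola balthica	F	trnM	65	.	.
MN528028	Limecola balthica	F	atp8	129	ATT	TAA
MN528028	Limecola balthica	F	trnS1	69	.	.
MN528028	Limecola balthica	F	nad6	510	ATA	TAA
MN528028	Limecola balthica	F	rrnL	1249	.	.
MN528028	Limecola balthica	F	atp6	735	ATG	TAA
MN528028	Limecola balthica	F	cox3	882	ATA	TAA
MN528028	Limecola balthica	F	nad2	990	ATG	TAA
MN528028	Limecola balthica	F	trnP	66	.	.
MN528028	Limecola balthica	F	trnQ	66	.	.
MN528028	Limecola balthica	F	trnC	61	.	.
MN528028	Limecola balthica	F	trnA	67	.	.
MN528028	Limecola balthica	F	trnF	66	.	.
MN528029	Limecola balthica	M	cox1	1536	ATT	TAA
MN528029	Limecola balthica	M	nad4	1341	TTG	TAA
MN528029	Limecola balthica	M	trnH	64	.	.
MN528029	Limecola balthica	M	trnS2	64	.	.
MN528029	Limecola balthica	M	trnE	66	.	.
MN528029	Limecola balthica	M	nad3	348	ATG	TAA
MN528029	Limecola balthica	M	trnI	68	.	.
MN528029	Limecola balthica	M	trnK	65	.	.
MN528029	Limecola balthica	M	nad4L	276	TTG	TAG
MN528029	Limecola balthica	M	trnY	67	.	.
MN528029	Limecola balthica	M	trnA_1	71	.	.
MN528029	Limecola balthica	M	trnL1	65	.	.
MN528029	Limecola balthica	M	trnD	65	.	.
MN528029	Limecola balthica	M	trnL2	65	.	.
MN528029	Limecola balthica	M	nad1	927	ATA	TAG
MN528029	Limecola balthica	M	trnN	65	.	.
MN528029	Limecola balthica	M	nad5	1767	ATA	TAG
MN528029	Limecola balthica	M	trnR	65	.	.
MN528029	Limecola balthica	M	cob	1137	ATA	TAA
MN528029	Limecola balthica	M	cox2	4815	ATG	T**
MN528029	Limecola balthica	M	trnV	65	.	.
MN528029	Limecola balthica	M	trnW	67	.	.
MN528029	Limecola balthica	M	trnG	66	.	.
MN528029	Limecola balthica	M	rrnS	886	.	.
MN528029	Limecola balthica	M	trnM	64	.	.
MN528029	Limecola balthica	M	atp8	130	TTG	T**
MN528029	Limecola balthica	M	trnS1	69	.	.
MN528029	Limecola balthica	M	nad6	513	TTG	TAG
MN528029	Limecola balthica	M	rrnL	1379	.	.
MN528029	Limecola balthica	M	atp6	741	GTG	TAG
MN528029	Limecola balthica	M	cox3	885	GTG	TAA
MN528029	Limecola balthica	M	nad2	987	ATG	TAG
MN528029	Limecola balthica	M	trnP_1	64	.	.
MN528029	Limecola balthica	M	trnP_0	65	.	.
MN528029	Limecola balthica	M	trnQ	66	.	.
MN528029	Limecola balthica	M	trnC	63	.	.
MN528029	Limecola balthica	M	trnA_0	66	.	.
MN528029	Limecola balthica	M	trnF	65	.	.
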