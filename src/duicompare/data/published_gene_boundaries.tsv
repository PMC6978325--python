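genome	upstream	downstream	intergenic_nt
MN528026	cox1	nad4	10
MN528026	nad4	trnH	2
MN528026	trnH	trnS2	0
MN528026	trnS2	trnE	0
MN528026	trnE	nad3	15
MN528026	nad3	trnI	10
MN528026	trnI	trnK	3
MN528026	trnK	nad4L	0
MN528026	nad4L	trnY	1
MN528026	trnY	trnT	-3
MN528026	trnT	trnL1	0
MN528026	trnL1	trnD	-1
MN528026	trnD	trnL2	2
MN528026	trnL2	nad1	1
MN528026	nad1	trnN	3
MN528026	trnN	nad5	0
MN528026	nad5	trnR	-40
MN528026	trnR	cob	3
MN528026	cob	cox2	110
MN528026	cox2	trnV	5
MN528026	trnV	trnW	0
MN528026	trnW	trnG	2
MN528026	trnG	rrnS	4
MN528026	rrnS	trnM	732
MN528026	trnM	atp8	11
MN528026	atp8	trnS1	-2
MN528026	trnS1	nad6	32
MN528026	nad6	rrnL	0
MN528026	rrnL	atp6	54
MN528026	atp6	cox3	30
MN528026	cox3	nad2	34
MN528026	nad2	trnP	52
MN528026	trnP	trnQ	11
MN528026	trnQ	trnC	15
MN528026	trnC	trnA	0
MN528026	trnA	trnF	-1
MN528026	trnF	cox1	161
MN528027	cox1	nad4	60
MN528027	nad4	trnH	4
MN528027	trnH	trnS2	55
MN528027	trnS2	trnE	15
MN528027	trnE	nad3	6
MN528027	nad3	trnI	-17
MN528027	trnI	trnK	1
MN528027	trnK	nad4L	2
MN528027	nad4L	trnY	7
MN528027	trnY	trnT	-2
MN528027	trnT	trnL1	1
MN528027	trnL1	trnD	-1
MN528027	trnD	trnL2	2
MN528027	trnL2	nad1	1
MN528027	nad1	trnN	-19
MN528027	trnN	nad5	25
MN528027	nad5	trnR	4
MN528027	trnR	cob	72
MN528027	cob	trnW	610
MN528027	trnW	rrnS	3231
MN528027	rrnS	trnV	101
MN528027	trnV	trnG	18
MN528027	trnG	cox2	1272
MN528027	cox2	trnM	57
MN528027	trnM	atp8	13
MN528027	atp8	trnS1	28
MN528027	trnS1	nad6	20
MN528027	nad6	rrnL	0
MN528027	rrnL	atp6	180
MN528027	atp6	cox3	8
MN528027	cox3	nad2	56
MN528027	nad2	trnP	3
MN528027	trnP	trnQ	25
MN528027	trnQ	trnC	0
MN528027	trnC	trnA	4
MN528027	trnA	trnF	3
MN528027	trnF	cox1	372
MN528028	cox1	nad4	0
MN528028	nad4	trnH	6
MN528028	trnH	trnS2	1
MN528028	trnS2	trnE	1
MN528028	trnE	nad3	15
MN528028	nad3	trnI	13
MN528028	trnI	trnK	2
MN528028	trnK	nad4L	0
MN528028	nad4L	trnY	4
MN528028	trnY	trnT	-2
MN528028	trnT	trnL1	0
MN528028	trnL1	trnD	-1
MN528028	trnD	trnL2	1
MN528028	trnL2	nad1	1
MN528028	nad1	trnN	1
MN528028	trnN	nad5	0
MN528028	nad5	trnR	1
MN528028	trnR	cob	31
MN528028	cob	cox2	71
MN528028	cox2	trnV	3
MN528028	trnV	trnW	-1
MN528028	trnW	trnG	5
MN528028	trnG	rrnS	3
MN528028	rrnS	trnM	1890
MN528028	trnM	atp8	9
MN528028	atp8	trnS1	3
MN528028	trnS1	nad6	34
MN528028	nad6	rrnL	35
MN528028	rrnL	atp6	47
MN528028	atp6	cox3	52
MN528028	cox3	nad2	81
MN528028	nad2	trnP	0
MN528028	trnP	trnQ	13
MN528028	trnQ	trnC	-1
MN528028	trnC	trnA	1
MN528028	trnA	trnF	-1
MN528028	trnF	cox1	163
MN528029	cox1	nad4	15
MN528029	nad4	trnH	13
MN528029	trnH	trnS2	16
MN528029	trnS2	trnE	2
MN528029	trnE	nad3	18
MN528029	nad3	trnI	-17
MN528029	trnI	trnK	2
MN528029	trnK	nad4L	10
MN528029	nad4L	trnY	1
MN528029	trnY	trnA_1	-2
MN528029	trnA_1	trnL1	3
MN528029	trnL1	trnD	-1
MN528029	trnD	trnL2	6
MN528029	trnL2	nad1	-14
MN528029	nad1	trnN	5
MN528029	trnN	nad5	0
MN528029	nad5	trnR	-10
MN528029	trnR	cob	111
MN528029	cob	cox2	216
MN528029	cox2	trnV	533
MN528029	trnV	trnW	0
MN528029	trnW	trnG	15
MN528029	trnG	rrnS	410
MN528029	rrnS	trnM	3697
MN528029	trnM	atp8	11
MN528029	atp8	trnS1	-1
MN528029	trnS1	nad6	-2
MN528029	nad6	rrnL	12
MN528029	rrnL	atp6	40
MN528029	atp6	cox3	17
MN528029	cox3	nad2	105
MN528029	nad2	trnP_1	78
MN528029	trnP_1	trnP_0	7
MN528029	trnP_0	trnQ	35
MN528029	trnQ	trnC	0
MN528029	trnC	trnA_0	13
MN528029	trnA_0	trnF	20
MN528029	trnF	cox1	250
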