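# Published gene organization of the Dendrolimus houi mitogenome (15,373 bp).
# Coordinates are 1-based inclusive; printed_gap is the interval/overlap value
# printed alongside each gene (gap to the preceding gene; blank where none was
# printed: the first gene and the control region).
genome_id	gene	type	strand	start	end	printed_gap
DH	trnM	tRNA	J	1	67
DH	trnI	tRNA	J	69	132	1
DH	trnQ	tRNA	N	130	198	-3
DH	ND2	PCG	J	230	1264	31
DH	trnW	tRNA	J	1263	1332	-2
DH	trnC	tRNA	N	1325	1391	-8
DH	trnY	tRNA	N	1393	1463	1
DH	COI	PCG	J	1524	3026	60
DH	trnL2	tRNA	J	3022	3088	-5
DH	COII	PCG	J	3089	3772	0
DH	trnK	tRNA	J	3774	3844	1
DH	trnD	tRNA	J	3846	3912	1
DH	ATP8	PCG	J	3913	4074	0
DH	ATP6	PCG	J	4071	4745	-4
DH	COIII	PCG	J	4762	5550	16
DH	trnG	tRNA	J	5553	5618	2
DH	ND3	PCG	J	5619	5972	0
DH	trnA	tRNA	J	5971	6038	-2
DH	trnR	tRNA	J	6048	6112	9
DH	trnN	tRNA	J	6117	6183	4
DH	trnS1	tRNA	J	6204	6269	20
DH	trnE	tRNA	J	6270	6338	0
DH	trnF	tRNA	N	6347	6413	8
DH	ND5	PCG	N	6418	8103	4
DH	trnH	tRNA	N	8161	8224	57
DH	ND4	PCG	N	8226	9563	1
DH	ND4L	PCG	N	9595	9861	31
DH	trnT	tRNA	J	9893	9957	31
DH	trnP	tRNA	N	9958	10022	0
DH	ND6	PCG	J	10040	10561	17
DH	CytB	PCG	J	10570	11715	8
DH	trnS2	tRNA	J	11719	11784	3
DH	ND1	PCG	N	11784	12713	-1
DH	trnL1	tRNA	N	12739	12806	25
DH	rrnL	rRNA	N	12847	14211	40
DH	trnV	tRNA	N	14211	14278	1
DH	rrnS	rRNA	N	14279	15054	0
DH	CR	control_region	J	15055	15373
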