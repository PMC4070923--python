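# Bactrocera minax mitogenome annotation (GenBank HM776033).
# Coordinates are 1-based inclusive on the circular 16,043 bp molecule.
# strand: F = majority (J) strand, R = minority (N) strand.
# genome_length=16043
gene	strand	start	end	kind	size	anticodon
trnI	F	1	65	tRNA	65	GAT
trnQ	R	66	134	tRNA	69	TTG
trnM	F	145	213	tRNA	69	CAT
nad2	F	213	1235	PCG	1023
trnW	F	1244	1311	tRNA	68	TCA
trnC	R	1304	1365	tRNA	62	GCA
trnY	R	1408	1475	tRNA	68	GTA
cox1	F	1474	3009	PCG	1536
trnL2	F	3009	3072	tRNA	64	TAA
cox2	F	3078	3764	PCG	687
trnK	F	3771	3841	tRNA	71	CTT
trnD	F	3841	3908	tRNA	68	GTC
atp8	F	3909	4070	PCG	162
atp6	F	4064	4741	PCG	678
cox3	F	4741	5532	PCG	792
trnG	F	5539	5604	tRNA	66	TCC
nad3	F	5605	5956	PCG	352
trnA	F	5957	6021	tRNA	65	TGC
trnR	F	6027	6090	tRNA	64	TCG
trnN	F	6119	6183	tRNA	65	GTT
trnS1	F	6184	6251	tRNA	68	GCT
trnE	F	6254	6319	tRNA	66	TTC
trnF	R	6338	6403	tRNA	66	GAA
nad5	R	6403	8122	PCG	1720
trnH	R	8137	8201	tRNA	65	GTG
nad4	R	8206	9546	PCG	1341
nad4l	R	9530	9826	PCG	297
trnT	F	9829	9893	tRNA	65	TGT
trnP	R	9894	9959	tRNA	66	TGG
nad6	F	9962	10483	PCG	522
cob	F	10483	11619	PCG	1137
trnS2	F	11618	11684	tRNA	67	TGA
nad1	R	11701	12640	PCG	940
trnL1	R	12651	12716	tRNA	66	TAG
rrnL	R	12717	14049	rRNA	1333
trnV	R	14049	14120	tRNA	72	TAC
rrnS	R	14121	14902	rRNA	782
CR	F	14903	16043	CR	1141
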