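name	start	end	type	strand	frame_offset
D-loop	1	576	D-loop	H	
TRNF	577	647	tRNA	H	
RNR1	648	1601	rRNA	H	
TRNV	1602	1670	tRNA	H	
RNR2	1671	3229	rRNA	H	
TRNL1	3230	3304	tRNA	H	
intergenic_3305_3306	3305	3306	intergenic	H	
ND1	3307	4262	CDS	H	0
TRNI	4263	4331	tRNA	H	
TRNQ	4329	4400	tRNA	L	
intergenic_4401_4401	4401	4401	intergenic	H	
TRNM	4402	4469	tRNA	H	
ND2	4470	5511	CDS	H	0
TRNW	5512	5579	tRNA	H	
intergenic_5580_5586	5580	5586	intergenic	H	
TRNA	5587	5655	tRNA	L	
intergenic_5656_5656	5656	5656	intergenic	H	
TRNN	5657	5729	tRNA	L	
intergenic_5730_5760	5730	5760	intergenic	H	
TRNC	5761	5826	tRNA	L	
TRNY	5826	5891	tRNA	L	
intergenic_5892_5903	5892	5903	intergenic	H	
CO1	5904	7445	CDS	H	0
TRNS1	7446	7514	tRNA	L	
intergenic_7515_7517	7515	7517	intergenic	H	
TRND	7518	7585	tRNA	H	
CO2	7586	8269	CDS	H	0
intergenic_8270_8294	8270	8294	intergenic	H	
TRNK	8295	8364	tRNA	H	
intergenic_8365_8365	8365	8365	intergenic	H	
ATP8	8366	8572	CDS	H	0
ATP6	8527	9207	CDS	H	0
CO3	9207	9990	CDS	H	0
TRNG	9991	10058	tRNA	H	
ND3	10059	10404	CDS	H	0
TRNR	10405	10469	tRNA	H	
ND4L	10470	10766	CDS	H	0
ND4	10760	12137	CDS	H	0
TRNH	12138	12206	tRNA	H	
TRNS2	12207	12265	tRNA	H	
TRNL2	12266	12336	tRNA	H	
ND5	12337	14148	CDS	H	0
ND6	14149	14673	CDS	L	0
TRNE	14674	14742	tRNA	L	
intergenic_14743_14746	14743	14746	intergenic	H	
CYB	14747	15887	CDS	H	0
TRNT	15888	15953	tRNA	H	
intergenic_15954_15955	15954	15955	intergenic	H	
TRNP	15956	16023	tRNA	L	
D-loop	16024	16569	D-loop	H	
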