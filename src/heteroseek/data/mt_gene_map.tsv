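# rCRS-style mitochondrial gene map: gene, start, end, strand, class
# 1-based closed intervals; the D-loop wraps the origin and is stored as
# two intervals sharing one name. Versioned configuration, not ground truth.
D-loop	16024	16569	+	D-loop
D-loop	1	576	+	D-loop
TRNF	577	647	+	tRNA
RNR1	648	1601	+	rRNA
TRNV	1602	1670	+	tRNA
RNR2	1671	3229	+	rRNA
TRNL1	3230	3304	+	tRNA
ND1	3307	4262	+	protein
TRNI	4263	4331	+	tRNA
TRNQ	4329	4400	-	tRNA
TRNM	4402	4469	+	tRNA
ND2	4470	5511	+	protein
TRNW	5512	5579	+	tRNA
TRNA	5587	5655	-	tRNA
TRNN	5657	5729	-	tRNA
TRNC	5761	5826	-	tRNA
TRNY	5826	5891	-	tRNA
CO1	5904	7445	+	protein
TRNS1	7446	7514	-	tRNA
TRND	7518	7585	+	tRNA
CO2	7586	8269	+	protein
TRNK	8295	8364	+	tRNA
ATP8	8366	8572	+	protein
ATP6	8527	9207	+	protein
CO3	9208	9990	+	protein
TRNG	9991	10058	+	tRNA
ND3	10059	10404	+	protein
TRNR	10405	10469	+	tRNA
ND4L	10470	10766	+	protein
ND4	10760	12137	+	protein
TRNH	12138	12206	+	tRNA
TRNS2	12207	12265	+	tRNA
TRNL2	12266	12336	+	tRNA
ND5	12337	14148	+	protein
ND6	14149	14673	-	protein
TRNE	14674	14742	-	tRNA
CYB	14747	15887	+	protein
TRNT	15888	15953	+	tRNA
TRNP	15956	16023	-	tRNA
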