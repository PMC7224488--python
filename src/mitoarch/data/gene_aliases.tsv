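# alias	canonical
# Editable map from annotation-source gene names to canonical symbols.
# Matching is case-insensitive and ignores punctuation/whitespace.
NAD1	ND1
NAD2	ND2
NAD3	ND3
NAD4	ND4
NAD4L	ND4L
NAD5	ND5
NAD6	ND6
NADH1	ND1
NADH2	ND2
NADH3	ND3
NADH4	ND4
NADH4L	ND4L
NADH5	ND5
NADH6	ND6
NADH dehydrogenase subunit 1	ND1
NADH dehydrogenase subunit 2	ND2
NADH dehydrogenase subunit 3	ND3
NADH dehydrogenase subunit 4	ND4
NADH dehydrogenase subunit 4L	ND4L
NADH dehydrogenase subunit 5	ND5
NADH dehydrogenase subunit 6	ND6
COX1	COI
COX2	COII
COX3	COIII
CO1	COI
CO2	COII
CO3	COIII
COXI	COI
COXII	COII
COXIII	COIII
cytochrome c oxidase subunit I	COI
cytochrome c oxidase subunit II	COII
cytochrome c oxidase subunit III	COIII
cytochrome oxidase subunit 1	COI
cytochrome oxidase subunit 2	COII
cytochrome oxidase subunit 3	COIII
ATPase6	ATP6
ATPase8	ATP8
ATP synthase F0 subunit 6	ATP6
ATP synthase F0 subunit 8	ATP8
COB	CytB
CYTB	CytB
CYB	CytB
cytochrome b	CytB
l-rRNA	rrnL
s-rRNA	rrnS
lrRNA	rrnL
srRNA	rrnS
rRNAL	rrnL
rRNAS	rrnS
rrn16	rrnL
rrn12	rrnS
16S	rrnL
12S	rrnS
16S rRNA	rrnL
12S rRNA	rrnS
16S ribosomal RNA	rrnL
12S ribosomal RNA	rrnS
large subunit ribosomal RNA	rrnL
small subunit ribosomal RNA	rrnS
D-loop	CR
control region	CR
A+T-rich region	CR
AT-rich region	CR
misc_feature	CR
tRNA-Ala	trnA
tRNA-Cys	trnC
tRNA-Asp	trnD
tRNA-Glu	trnE
tRNA-Phe	trnF
tRNA-Gly	trnG
tRNA-His	trnH
tRNA-Ile	trnI
tRNA-Lys	trnK
tRNA-Met	trnM
tRNA-Asn	trnN
tRNA-Pro	trnP
tRNA-Gln	trnQ
tRNA-Arg	trnR
tRNA-Thr	trnT
tRNA-Val	trnV
tRNA-Trp	trnW
tRNA-Tyr	trnY
tRNAsn	trnN
tRNA-Leu(UUR)	trnL2
tRNA-Leu(UUN)	trnL2
tRNA-Leu(TAA)	trnL2
tRNA-Leu(UAA)	trnL2
tRNA-Leu2	trnL2
tRNALeu2	trnL2
tRNA-Leu(CUN)	trnL1
tRNA-Leu(TAG)	trnL1
tRNA-Leu(UAG)	trnL1
tRNA-Leu1	trnL1
tRNALeu1	trnL1
tRNA-Ser(AGN)	trnS1
tRNA-Ser(GCT)	trnS1
tRNA-Ser(GCU)	trnS1
tRNA-Ser1	trnS1
tRNASer1	trnS1
tRNA-Ser(UCN)	trnS2
tRNA-Ser(TGA)	trnS2
tRNA-Ser(UGA)	trnS2
tRNA-Ser2	trnS2
tRNASer2	trnS2
trnL(UUR)	trnL2
trnL(CUN)	trnL1
trnS(AGN)	trnS1
trnS(UCN)	trnS2
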