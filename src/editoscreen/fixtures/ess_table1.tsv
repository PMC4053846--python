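species	chrom	pos	strand	gene	region	substitution	source
human	chr1	160302244	-	COPA	CDS	NM_001098398:c.A490G:p.I164V	table1
human	chr11	105804694	+	GRIA4	CDS	NM_000829:c.A2293G:p.R765G	table1
human	chr11	105815132	+	GRIA4	intron		table1
human	chr11	105816106	+	GRIA4	intron		table1
human	chr11	105816129	+	GRIA4	intron		table1
human	chr11	105816145	+	GRIA4	intron		table1
human	chr11	105816160	+	GRIA4	intron		table1
human	chr12	5021742	+	KCNA1	CDS	NM_000217:c.A1198G:p.I400V	table1
human	chr13	46090371	+	COG3	CDS	NM_031431:c.A1903G:p.I635V	table1
human	chr14	26917530	-	NOVA1	CDS	NM_006489:c.A1087G:p.S363G	table1
human	chr14	101506074	+	mir376C	microRNA		table1
human	chr17	43045220	-	C1QL1	CDS	NM_006688:c.A197G:p.Q66R	table1
human	chr19	47152854	-	DACT3	CDS	NM_145056:c.A775G:p.R259G	table1
human	chr2	20450819	-	PUM2	3UTR		table1
human	chr2	21233202	-	APOB	CDS	NM_000384:c.C6538G:p.Q2180stop	table1
human	chr2	210835613	+	UNC80	CDS	NM_032504:c.A7990G:p.S2664G	table1
human	chr20	36147533	-	BLCAP	CDS	NM_001167821:c.A44G:p.K15R	table1
human	chr20	36147563	-	BLCAP	CDS	NM_001167821:c.A14G:p.Q5R	table1
human	chr20	36147572	-	BLCAP	CDS	NM_001167821:c.A5G:p.Y2C	table1
human	chr20	36148080	-	BLCAP	intron		table1
human	chr20	52104918	+	TSHZ2	3UTR		table1
human	chr21	30953750	-	GRIK1	CDS	NM_175611:c.A1862G:p.Q621R	table1
human	chr21	34922801	+	SON	CDS	NM_032195:c.A1264G:p.T422A	table1
human	chr21	34923319	+	SON	CDS	NM_032195:c.A1782G:p.L594L	table1
human	chr21	46595620	+	ADARB1	intron		table1
human	chr3	53820892	+	CACNA1D	CDS	NM_001128839:c.A4791G:p.I1597M	table1
human	chr3	58141801	+	FLNB	CDS	NM_001164319:c.A6815G:p.Q2272R	table1
human	chr3	62423807	-	CADPS	CDS	NM_183393:c.A3512G:p.E1171G	table1
human	chr4	57976234	-	IGFBP7	CDS	NM_001253835:c.A284G:p.K95R	table1
human	chr4	57976286	-	IGFBP7	CDS	NM_001253835:c.A232G:p.R78G	table1
human	chr4	158257875	+	GRIA2	CDS	NM_000826:c.A1820G:p.Q607R	table1
human	chr4	158257879	+	GRIA2	CDS		table1
human	chr4	158258136	+	GRIA2	intron		table1
human	chr4	158258137	+	GRIA2	intron		table1
human	chr4	158281294	+	GRIA2	CDS	NM_000826:c.A2290G:p.R764G	table1
human	chr5	156736808	+	CYFIP2	CDS	NM_001037332:c.A958G:p.K320E	table1
human	chr6	34100903	-	GRM4	CDS	NM_000841:c.A371G:p.Q124R	table1
human	chr6	44120349	+	TMEM63B	CDS	NM_018426:c.A1856G:p.Q619R	table1
human	chr6	102337689	+	GRIK2	CDS	NM_001166247:c.A1699G:p.I567V	table1
human	chr6	102337702	+	GRIK2	CDS	NM_001166247:c.A1712G:p.Y571C	table1
human	chr6	102372589	+	GRIK2	CDS	NM_001166247:c.A1862G:p.Q621R	table1
human	chr6	102372630	+	GRIK2	intron		table1
human	chr6	102374616	+	GRIK2	intron		table1
human	chr6	102374643	+	GRIK2	intron		table1
human	chr6	150093334	+	PCMT1	intron		table1
human	chr8	103841636	-	AZIN1	CDS	NM_148174:c.A1099G:p.S367G	table1
human	chr8	103841637	-	AZIN1	CDS	NM_148174:c.A1098G:p.E366E	table1
human	chr9	97847739	+	mir23B	microRNA		table1
human	chrX	114082682	+	HTR2C	CDS	NM_000868:c.A466G:p.I156V	table1
human	chrX	114082684	+	HTR2C	CDS	NM_000868:c.A468G:p.I156M	table1
human	chrX	114082689	+	HTR2C	CDS	NM_000868:c.A473G:p.N158S	table1
human	chrX	114082694	+	HTR2C	CDS	NM_000868:c.A478G:p.I160V	table1
human	chrX	122598962	+	GRIA3	CDS	NM_000828:c.A2323G:p.R775G	table1
human	chrX	122598998	+	GRIA3	intron		table1
human	chrX	135111055	+	SLC9A6	intron		table1
human	chrX	135111070	+	SLC9A6	intron		table1
human	chrX	151358319	-	GABRA3	CDS	NM_000808:c.A1026G:p.I342M	table1
human	chrX	153579737	-	FLNA	intron		table1
human	chrX	153579950	-	FLNA	CDS	NM_001456:c.A6998G:p.Q2333R	table1
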