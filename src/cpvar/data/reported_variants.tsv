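case_id	group	genes	variant	variant_class	consequence	inheritance	pop_freq	cadd	acmg_class	clinical_significance	mechanism	risk_allele	primary
P169	causative	GRIN2B	NM_000834.3:c.1739T>A:p.F580Y	SNV	nonsynonymous	unknown	0	29.8	likely_pathogenic	causative	ad_missense	0	1
P176	causative	ARHGAP31	NM_020754.2:c.1699del:p.P567Rfs*28	indel	frameshift	maternal	0	NA	likely_pathogenic	causative	ad_lof	0	1
P178	causative	MFN2	NM_001127660.1:c.2220G>A:p.W740*	SNV	stopgain	paternal	0	54	likely_pathogenic	causative	ad_lof	0	1
P185	causative	CLCN2	NM_001171088.3:c.1598G>A:p.R533Q	SNV	nonsynonymous	unknown	2.00e-4	24	likely_pathogenic	causative	ad_missense	0	1
P185	causative	CACNA1C	NM_000719.7:c.3568G>T:p.V1190L	SNV	nonsynonymous	unknown	1.22e-5	27.6	likely_pathogenic	causative	NA	0	0
P205	causative	CFTR	NM_000492.4:c.1520-22del:p.P508del	indel	nonframeshift_indel	biparental	7.17e-3	21.3	pathogenic	causative	ar	0	1
P205	causative	CLCN1	NM_000083.3:c.2680C>T:p.R894*	SNV	stopgain	not_maternal	3.18e-3	35	pathogenic	causative	NA	0	0
P217	causative	SPAST	Chr2:32347645_32354557del	CNV_del	cnv	paternal	0	NA	pathogenic	causative	cnv	0	1
P217	causative	SPAST	NM_014946.4:c.131C>T:p.S44L	SNV	nonsynonymous	maternal	4.54e-3	21.2	modifier	modifier	NA	0	0
P225	causative	SPAST	NM_014946.3:c.1625A>G:p.D542G	SNV	nonsynonymous	maternal	4.13e-4	21.2	likely_pathogenic	causative	ad_missense	0	1
P233	causative	SYNE2	NM_015180.4:c.16153C>T:p.Q5385*	SNV	stopgain	unknown	0	44	pathogenic	causative	ad_lof	0	1
P236	causative	TUBB4A	NM_006087.4:c.1228G>A:p.E410K	SNV	nonsynonymous	de_novo	0	27.5	pathogenic	causative	ad_missense	0	1
P708	causative	KLHL3	NM_001257195.1:c.1446G>A:p.W482*	SNV	stopgain	not_maternal	0	38	pathogenic	causative	ad_lof	0	1
P712	causative	NF1	Chr17:28992701_30408700del	CNV_del	cnv	unknown	0	NA	pathogenic	causative	cnv	0	1
P715	causative	TTN	NM_001267550.2:c.50473C>T:p.Q16825*	SNV	stopgain	maternal	0	61	pathogenic	causative	ad_lof	0	1
P750	causative	VCX3A,STS,PNPLA4	ChrX:6451301_8138000del	CNV_del	cnv	unknown	0	NA	pathogenic	causative	cnv	0	1
P754	causative	KIDINS220	NM_020738.2:c.4497del:p.R1499Sfs*9	indel	frameshift	not_maternal	0	NA	likely_pathogenic	causative	ad_lof	0	1
P756	causative	CACNA1A	NM_001127222.2:c.7249G>T:p.E2417*	SNV	stopgain	not_maternal	0	40	likely_pathogenic	causative	ad_lof	0	1
P759	causative	SETX	NM_015046.7:c.5821_5830del:p.A1941Lfs*6	indel	frameshift	not_maternal	0	NA	pathogenic	causative	ad_lof	0	1
P763	causative	CPA6	NM_020361.5:c.799G>A:p.G267R	SNV	nonsynonymous	unknown	2.06e-3	29.1	likely_pathogenic	causative	ar	0	1
P763	causative	CPA6	NM_020361.5:c.619C>G:p.Q207E	SNV	nonsynonymous	unknown	1.43e-3	26.2	likely_pathogenic	causative	NA	0	0
P763	causative	STRADA	NM_001003787.4:c.95-2A>C	SNV	splicing	unknown	8.23e-6	25.8	likely_pathogenic	uncertain	NA	0	0
P784	causative	GNB1	NM_002074.5:c.239T>C:p.I80T	SNV	nonsynonymous	unknown	3.98e-6	25.6	likely_pathogenic	causative	ad_missense	0	1
P792	causative	COL4A1	NM_001845.4:c.1258G>A:p.G420R	SNV	nonsynonymous	unknown	0	18.3	likely_pathogenic	causative	ad_missense	0	1
P910	causative	TUBA1A	NM_006009.3:c.50G>A:p.G17D	SNV	nonsynonymous	unknown	0	29.2	likely_pathogenic	causative	ad_missense	0	1
P911	causative	COL4A2	NM_001846.2:c.3625G>A:p.G1209R	SNV	nonsynonymous	paternal	0	24.7	likely_pathogenic	causative	ad_missense	0	1
P931	causative	ALDH3A2	NM_000382.3:c.941_943delinsGGGCTAAAAGTACTGTTGGGG:p.A314_P315delinsGAKSTVGA	indel	nonframeshift_indel	biparental	0	NA	pathogenic	causative	ar	0	1
P939	causative	PDGFRB	NM_002609.3:c.2083C>T:p.R695C	SNV	nonsynonymous	maternal	1.13e-4	32	likely_pathogenic	causative	blended	0	1
P939	causative	PROC	NM_000312.3:c.226G>A:p.V76M	SNV	nonsynonymous	not_maternal	4.96e-5	21.2	likely_pathogenic	causative	NA	0	0
P965	causative	COL4A1	NM_001845.4:c.4114G>C:p.G1372R	SNV	nonsynonymous	unknown	0	23.9	pathogenic	causative	ad_missense	0	1
P972	causative	MT-TL1	NC_012920.1:m.3243A>G	SNV	noncoding	maternal	NA	NA	pathogenic	causative	mt	0	1
P980	causative	22q11.2	Chr22:18873001_21469900dup	CNV_dup	cnv	unknown	0	NA	likely_pathogenic	causative	cnv	0	1
P1110	causative	COL4A2	NM_001846.2:c.957+2T>C	SNV	splicing	not_maternal	0	25	likely_pathogenic	causative	ad_lof	0	1
P1138	causative	COL4A2	NM_001846.2:c.4049G>A:p.G1350D	SNV	nonsynonymous	maternal	0	25.6	likely_pathogenic	causative	ad_missense	0	1
P165	risk_factor	TRIM32,ASTN2	Chr9:119311659_119462832del	CNV_del	cnv	unknown	0	NA	likely_pathogenic	risk_factor	cnv	0	1
P165	risk_factor	HTT	NM_002111.8:c.7731G>A:p.W2577*	SNV	stopgain	unknown	0	52	pathogenic	uncertain	NA	0	0
P199	risk_factor	F8	NM_000132.3:c.5146C>A:p.H1716N	SNV	nonsynonymous	unknown	0	25.5	likely_pathogenic	risk_factor	xl	0	1
P214	risk_factor	15q11-q13	Chr15:22722801_26749200dup	CNV_dup	cnv	unknown	0	NA	pathogenic	risk_factor	cnv	1	1
P710	risk_factor	F2	NM_000506.5:c.*97G>A	SNV	noncoding	unknown	8.44e-3	NA	likely_pathogenic	risk_factor	ad_lof	1	1
P747	risk_factor	F2	NM_001311257:c.*97G>A	SNV	noncoding	unknown	8.44e-3	NA	likely_pathogenic	risk_factor	ad_lof	1	1
P752	risk_factor	NKX2-6	NM_001136271.3:c.455dup:p.Q153Afs*207	indel	frameshift	maternal	3.15e-5	30	pathogenic	risk_factor	ad_lof	0	1
P779	risk_factor	F2	NM_000506.3:c.598G>A:p.E200K	SNV	nonsynonymous	unknown	1.20e-3	NA	risk_factor	risk_factor	ad_missense	1	1
P795	risk_factor	F2	NM_001311257:c.*97G>A	SNV	noncoding	unknown	8.44e-3	NA	likely_pathogenic	risk_factor	ad_lof	1	1
P1147	risk_factor	1q21.1	Chr1:145382601_145616000del	CNV_del	cnv	unknown	0	NA	pathogenic	risk_factor	cnv	1	1
P182	uncertain	GALC	NM_000153.4:c.1592G>A:p.R531H	SNV	nonsynonymous	paternal	3.24e-5	29.4	pathogenic	uncertain	NA	0	1
P182	uncertain	GALC	NM_000153.4:c.334A>G:p.T112A	SNV	nonsynonymous	not_paternal	2.50e-3	23	likely_pathogenic	uncertain	NA	0	0
P188	uncertain	COL4A4	NM_000092.5:c.4720C>T:p.Q1574*	SNV	stopgain	unknown	0	46	pathogenic	uncertain	NA	0	1
P228	uncertain	ASTN2	NM_014010.4:c.2317C>T:p.Q773*	SNV	stopgain	paternal	0	46	pathogenic	uncertain	NA	0	1
P232	uncertain	EGFR	NM_005228.3:c.925C>T:p.R309*	SNV	stopgain	de_novo	0	38	pathogenic	uncertain	NA	0	1
P703	uncertain	SPG7	NM_003119.2:c.1045G>A:p.G349S	SNV	nonsynonymous	unknown	8.23e-4	26.7	likely_pathogenic	uncertain	NA	0	1
P760	uncertain	PNPLA6	NM_001166114.2:c.3058_3061dup:p.R1021Qfs*38	indel	frameshift	unknown	1.25e-4	35	pathogenic	uncertain	NA	0	1
P760	uncertain	PNPLA6	NM_001166114.2:c.1144del:p.A383Pfs*11	indel	frameshift	unknown	0	NA	pathogenic	uncertain	NA	0	0
P778	uncertain	VWF	NM_000552.4:c.2561G>A:p.R854Q	SNV	nonsynonymous	unknown	3.47e-3	33	pathogenic	uncertain	NA	0	1
P1106	uncertain	PIEZO2	NM_022068.2:c.1444del:p.R482Efs*16	indel	frameshift	not_maternal	0	NA	likely_pathogenic	uncertain	NA	0	1
P1132	uncertain	BUB1B	NM_001211.5:c.1526C>A:p.S509*	SNV	stopgain	maternal	0	36	pathogenic	uncertain	NA	0	1
P741	incidental	MITF	NM_006722.2:c.1018C>T:p.R340C	SNV	nonsynonymous	unknown	0	33	likely_pathogenic	incidental	NA	0	1
P746	incidental	ABCA4	NM_000350.2:c.6316C>T:p.R2106C	SNV	nonsynonymous	unknown	1.31e-4	33	pathogenic	incidental	NA	0	1
P746	incidental	ABCA4	NM_000350.2:c.5282C>G:p.P1761R	SNV	nonsynonymous	unknown	0	26.5	likely_pathogenic	incidental	NA	0	0
P749	incidental	GJB2	NM_004004.5:c.95G>A:p.R32H	SNV	nonsynonymous	paternal	3.99e-6	25.3	pathogenic	incidental	NA	0	1
P802	incidental	EFEMP1	NM_001039348.3:c.1033C>T:p.R345W	SNV	nonsynonymous	not_maternal	0	25.9	pathogenic	incidental	NA	0	1
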