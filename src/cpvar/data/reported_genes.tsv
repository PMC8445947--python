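gene	panels	missense_z	lof_oe	inheritance_mode	domino_label	penetrance_caveat	lof_mechanism	omim	aetiology
GRIN2B	DDG2P,ID	3.1	0.09	AD	very_likely_dominant	0	1	1	NDD
ARHGAP31	DDG2P	NA	NA	AD	likely_dominant	1	1	1	stroke_cardiovascular
MFN2	DDG2P	2.1	0.35	AD	very_likely_dominant	1	1	1	NDD
CLCN2	EPILEPSY	1.4	0.44	AD	likely_dominant	1	1	1	NDD
CACNA1C	DDG2P	4.2	0.1	AD	very_likely_dominant	1	0	1	NDD
CFTR		NA	NA	AR	very_likely_recessive	0	1	1	NDD
CLCN1	EPILEPSY	NA	NA	AD	likely_dominant	1	1	1	NDD
SPAST	DDG2P,CP	2.3	0.13	AD	very_likely_dominant	1	1	1	HSP
SYNE2		NA	NA	AD	likely_dominant	1	1	1	NDD
TUBB4A	DDG2P,CP	3.4	0.3	AD	very_likely_dominant	0	0	1	HSP
KLHL3		NA	NA	AD	likely_dominant	1	1	1	NDD
NF1	DDG2P	2.6	0.04	AD	very_likely_dominant	1	1	1	NDD
TTN		NA	0.36	AD	likely_dominant	1	1	1	stroke_cardiovascular
KIDINS220	DDG2P	2.2	0.1	AD	likely_dominant	1	1	1	HSP
CACNA1A	DDG2P,EPILEPSY	4.8	0.07	AD	very_likely_dominant	1	1	1	NDD
SETX		NA	NA	AD	likely_dominant	1	1	1	NDD
CPA6	EPILEPSY	NA	NA	AR	likely_recessive	0	0	1	NDD
STRADA	DDG2P,EPILEPSY	NA	NA	AR	very_likely_recessive	0	1	1	NDD
GNB1	DDG2P,ID	3.9	0.18	AD	very_likely_dominant	0	0	1	NDD
COL4A1	DDG2P,CP	2.4	0.27	AD	very_likely_dominant	1	0	1	stroke_cardiovascular
TUBA1A	DDG2P,CP	3.6	0.33	AD	very_likely_dominant	0	0	1	NDD
COL4A2	DDG2P,CP	2.1	0.41	AD	likely_dominant	1	0	1	stroke_cardiovascular
ALDH3A2	DDG2P	NA	NA	AR	very_likely_recessive	0	1	1	HSP
PDGFRB	DDG2P	2.8	0.21	AD	very_likely_dominant	1	0	1	stroke_cardiovascular
PROC		NA	NA	AD	likely_dominant	1	1	1	stroke_cardiovascular
MT-TL1		NA	NA	MT	NA	0	0	1	NDD
22q11.2		NA	NA	unknown	NA	1	0	1	NDD
TRIM32		NA	NA	AR	likely_recessive	1	1	1	NDD
ASTN2		2.0	0.45	AD	likely_dominant	1	1	1	NDD
HTT	DDG2P	3.2	0.11	AD	very_likely_dominant	1	0	1	NDD
F8		NA	NA	XL	NA	1	1	1	stroke_cardiovascular
15q11-q13		NA	NA	unknown	NA	1	0	1	NDD
F2		NA	NA	AD	likely_dominant	1	0	1	stroke_cardiovascular
NKX2-6		NA	NA	AD	likely_dominant	1	1	1	stroke_cardiovascular
1q21.1		NA	NA	unknown	NA	1	0	1	NDD
VCX3A		NA	NA	XL	NA	0	1	1	NDD
STS		NA	NA	XL	NA	0	1	1	NDD
PNPLA4		NA	NA	XL	NA	0	1	1	NDD
GALC		NA	NA	AR	very_likely_recessive	0	1	1	NA
COL4A4		1.2	0.52	AD	likely_dominant	1	0	1	NA
EGFR		2.9	0.15	AD	likely_dominant	0	0	1	NA
SPG7		NA	NA	AR	likely_recessive	0	1	1	NA
PNPLA6		NA	NA	AR	very_likely_recessive	0	1	1	NA
VWF		NA	NA	AD	likely_dominant	1	0	1	NA
PIEZO2	DDG2P	2.4	0.4	AR	likely_recessive	1	1	1	NA
BUB1B	DDG2P	NA	NA	AD	likely_dominant	1	1	1	NA
MITF		2.2	0.3	AD	likely_dominant	1	0	1	NA
ABCA4		NA	NA	AR	very_likely_recessive	0	1	1	NA
GJB2		NA	NA	AR	very_likely_recessive	0	1	1	NA
EFEMP1		NA	NA	AD	likely_dominant	1	0	1	NA
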