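n_families	gene
2	TMEM52
2	GCFC2
2	RTP5
2	SLC10A6
2	SAMD9L
2	PTPRD
2	ASCL1
2	GALC
2	CD34
2	ALPPL2
2	FAM189B
2	NTRK1
2	CHIT1
2	DCBLD2
2	COL6A5
2	ATG9B
2	NUTM2F
2	NME3
2	GFAP
2	KRTAP10-5
2	ZNF644
2	FLG
2	OR6P1
2	CSMD1
2	UQCRB
2	LMNTD2
2	THAP11
2	MLLT1
2	OR14A2
2	VWA3B
2	CFC1B
2	MSH3
2	AKAP3
2	GNB1L
2	RAB36
2	FGD1
2	THOC3
2	TNXB
2	AHNAK2
2	XYLT1
2	APOL3
2	CACFD1
2	RPL3L
2	PIGT
2	CTNNA3
2	LRIT1
2	TYMP
2	ASXL2
2	GPAT2
2	AARD
2	MGA
2	LGALS9C
2	C18orf65
2	AHCY
2	CSMD2
2	VPS41
2	BHLHE22
2	CCDC68
2	SYNJ1
2	HMGCS2
2	SYN2
2	DNASE1L3
2	CASP12
2	FSIP2
2	TET2
2	FAM153B
2	FAM153A
2	PFAS
2	PDZD2
2	KLHL32
2	ANKRD18A
2	MCM8
2	NPHP4
2	USP32
2	COL21A1
2	SSTR5
2	CEACAM21
2	FAM26F
2	OR4A5
2	KRT81
2	BDNF
2	SLC1A7
2	SPTA1
2	TNK2
2	PTPRE
2	CYB5R2
2	MTUS2
2	FANCA
2	KATNAL2
2	OTC
2	GPIHBP1
2	CLEC18B
2	SLC22A31
2	SETDB1
3	GPRIN1
3	SKIV2L
3	PRR23D1
3	TBC1D26
3	KIR3DL1
3	TTN
3	KRTAP4-3
3	DLL3
3	OBSCN
3	KCNQ5
3	CCDC168
3	PRR25
3	ANKRD11
3	HRC
3	GPR179
3	USP26
3	FCGBP
3	KCNN3
3	CACNA1H
3	ANKRD30B
3	KIAA1875
3	MRC1
3	ACOT4
3	KIAA0556
3	ERCC6L
3	DYSF
3	CEP170
3	AHNAK
4	POM121
4	PKD1L2
4	TMPRSS13
4	KRT2
4	ZNF717
4	PDE4DIP
5	AL589743.1
5	TPRX1
5	FAM47A
5	WIPF3
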