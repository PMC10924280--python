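source	target
Ackr1	ACKR1
Acta2	ACTA2
Adgre1	ADGRE1
Adora2a	ADORA2A
Afp	AFP
Aim2	AIM2
Alas2	ALAS2
Alb	ALB
Alox15	ALOX15
Alox5	ALOX5
Anpep	ANPEP
Apoa1	APOA1
Apob	APOB
Apoe	APOE
Arg1	ARG1
Arg2	ARG2
Arhgdib	ARHGDIB
Arx	ARX
Asgr1	ASGR1
Aurka	AURKA
Aurkb	AURKB
B2m	B2M
Bach2	BACH2
Bak1	BAK1
Batf	BATF
Batf3	BATF3
Bax	BAX
Bcl2	BCL2
Bcl2l1	BCL2L1
Bcl6	BCL6
Bhlhe40	BHLHE40
Birc5	BIRC5
Blk	BLK
Bst2	BST2
Btk	BTK
Btla	BTLA
Bub1	BUB1
C1qa	C1QA
C1qb	C1QB
C1qc	C1QC
C1r	C1R
C1s	C1S
C3	C3
C5ar1	C5AR1
Camp	CAMP
Card11	CARD11
Casp1	CASP1
Casp3	CASP3
Casp8	CASP8
Ccl17	CCL17
Ccl19	CCL19
Ccl2	CCL2
Ccl20	CCL20
Ccl21	CCL21
Ccl22	CCL22
Ccl3	CCL3
Ccl4	CCL4
Ccl5	CCL5
Ccl7	CCL7
Ccl8	CCL8
Ccnb1	CCNB1
Ccr1	CCR1
Ccr10	CCR10
Ccr2	CCR2
Ccr3	CCR3
Ccr4	CCR4
Ccr5	CCR5
Ccr6	CCR6
Ccr7	CCR7
Ccr8	CCR8
Ccr9	CCR9
Cd14	CD14
Cd160	CD160
Cd163	CD163
Cd19	CD19
Cd1d	CD1D
Cd2	CD2
Cd22	CD22
Cd226	CD226
Cd24	CD24
Cd244	CD244
Cd27	CD27
Cd274	CD274
Cd33	CD33
Cd34	CD34
Cd36	CD36
Cd37	CD37
Cd38	CD38
Cd3d	CD3D
Cd3e	CD3E
Cd3g	CD3G
Cd4	CD4
Cd40	CD40
Cd40lg	CD40LG
Cd44	CD44
Cd47	CD47
Cd48	CD48
Cd5	CD5
Cd52	CD52
Cd53	CD53
Cd55	CD55
Cd58	CD58
Cd59	CD59
Cd6	CD6
Cd68	CD68
Cd69	CD69
Cd7	CD7
Cd74	CD74
Cd79a	CD79A
Cd79b	CD79B
Cd80	CD80
Cd81	CD81
Cd83	CD83
Cd84	CD84
Cd86	CD86
Cd8a	CD8A
Cd8b1	CD8B
Cd9	CD9
Cd99	CD99
Cdh1	CDH1
Cdh5	CDH5
Cdk1	CDK1
Ceacam8	CEACAM8
Cebpa	CEBPA
Cebpb	CEBPB
Cebpe	CEBPE
Cfb	CFB
Cfd	CFD
Cfh	CFH
Cfp	CFP
Chga	CHGA
Chgb	CHGB
Ciita	CIITA
Cldn4	CLDN4
Cldn5	CLDN5
Cldn7	CLDN7
Clec4c	CLEC4C
Clec9a	CLEC9A
Cnn1	CNN1
Col1a1	COL1A1
Col1a2	COL1A2
Col3a1	COL3A1
Col5a1	COL5A1
Col6a1	COL6A1
Col6a2	COL6A2
Col6a3	COL6A3
Coro1a	CORO1A
Cpa3	CPA3
Cr2	CR2
Csf1	CSF1
Csf1r	CSF1R
Csf2	CSF2
Csf3	CSF3
Csf3r	CSF3R
Ctla4	CTLA4
Ctsg	CTSG
Cxcl1	CXCL1
Cxcl10	CXCL10
Cxcl11	CXCL11
Cxcl12	CXCL12
Cxcl13	CXCL13
Cxcl14	CXCL14
Cxcl15	CXCL8
Cxcl16	CXCL16
Cxcl2	CXCL2
Cxcl5	CXCL5
Cxcl9	CXCL9
Cxcr1	CXCR1
Cxcr2	CXCR2
Cxcr3	CXCR3
Cxcr4	CXCR4
Cxcr5	CXCR5
Cxcr6	CXCR6
Cyba	CYBA
Cybb	CYBB
Cyp3a4	CYP3A4
Dcn	DCN
Defa4	DEFA4
Derl3	DERL3
Des	DES
Dock2	DOCK2
Dock8	DOCK8
Ebf1	EBF1
Egfl7	EGFL7
Egr1	EGR1
Egr2	EGR2
Elane	ELANE
Emcn	EMCN
Enpp3	ENPP3
Entpd1	ENTPD1
Eomes	EOMES
Epb42	EPB42
Epcam	EPCAM
Epor	EPOR
Epx	EPX
Erg	ERG
Esam	ESAM
Ets1	ETS1
Evl	EVL
Fap	FAP
Fas	FAS
Faslg	FASLG
Fbln1	FBLN1
Fbln2	FBLN2
Fcar	FCAR
Fcer1a	FCER1A
Fcer1g	FCER1G
Fcer2	FCER2
Fcgr1a	FCGR1A
Fcgr2b	FCGR2B
Fcgr3	FCGR2A
Fcgr3b	FCGR3B
Fcgr4	FCGR3A
Fcgrt	FCGRT
Fcmr	FCMR
Fcn1	FCN1
Fermt3	FERMT3
Fga	FGA
Fgb	FGB
Fgg	FGG
Fgr	FGR
Flt1	FLT1
Flt3	FLT3
Flt4	FLT4
Fn1	FN1
Fosb	FOSB
Foxp3	FOXP3
Fpr1	FPR1
Gata1	GATA1
Gata1b	GATA1B
Gata2	GATA2
Gata2b	GATA2B
Gata3	GATA3
Gcg	GCG
Gfi1	GFI1
Gfi1b	GFI1B
Gm42418	RN7SK
Gp1ba	GP1BA
Gp9	GP9
Gsdmd	GSDMD
Gypa	GYPA
Gzma	GZMA
Gzmb	GZMB
Gzmk	GZMK
Gzmm	GZMM
H2-Aa	HLA-DQA1
H2-Ab1	HLA-DQB1
H2-D1	HLA-A
H2-Eb1	HLA-DRB1
H2-K1	HLA-C
Havcr2	HAVCR2
Hba1	HBA1
Hbb	HBB
Hck	HCK
Hdc	HDC
Hhex	HHEX
Hla-E	HLA-E
Hmox1	HMOX1
Hnf4a	HNF4A
Hoxa9	HOXA9
Hpgds	HPGDS
Iapp	IAPP
Icam1	ICAM1
Icam2	ICAM2
Icam3	ICAM3
Icos	ICOS
Id2	ID2
Id3	ID3
Ido1	IDO1
Ido2	IDO2
Ifi27l2a	IFI27
Ifi44l	IFI44L
Ifi6	IFI6
Ifit1	IFIT1
Ifit3	IFIT3
Ifng	IFNG
Ighm	IGHM
Ikzf1	IKZF1
Ikzf2	IKZF2
Ikzf3	IKZF3
Il10	IL10
Il12a	IL12A
Il12b	IL12B
Il12rb2	IL12RB2
Il13	IL13
Il15	IL15
Il17a	IL17A
Il17f	IL17F
Il18	IL18
Il18r1	IL18R1
Il18rap	IL18RAP
Il1b	IL1B
Il2	IL2
Il21	IL21
Il23a	IL23A
Il27	IL27
Il2ra	IL2RA
Il32	IL32
Il33	IL33
Il3ra	IL3RA
Il4	IL4
Il5	IL5
Il5ra	IL5RA
Il6	IL6
Il7r	IL7R
Ins	INS
Irf4	IRF4
Irf7	IRF7
Irf8	IRF8
Irx2	IRX2
Isg15	ISG15
Itga2b	ITGA2B
Itga4	ITGA4
Itga6	ITGA6
Itgae	ITGAE
Itgal	ITGAL
Itgam	ITGAM
Itgax	ITGAX
Itgb1	ITGB1
Itgb2	ITGB2
Itgb3	ITGB3
Itgb7	ITGB7
Itk	ITK
Jak1	JAK1
Jak2	JAK2
Jak3	JAK3
Jchain	JCHAIN
Junb	JUNB
Kdr	KDR
Kit	KIT
Kit2	KIT2
Klf1	KLF1
Klf2	KLF2
Klf4	KLF4
Klrb1c	KLRB1
Klrc1	KLRC1
Klrd1	KLRD1
Klrk1	KLRK1
Krt14	KRT14
Krt18	KRT18
Krt19	KRT19
Krt5	KRT5
Krt7	KRT7
Krt8	KRT8
Lag3	LAG3
Laptm5	LAPTM5
Lat	LAT
Lck	LCK
Lcn2	LCN2
Lef1	LEF1
Lgals1	LGALS1
Lgals3	LGALS3
Lgals9	LGALS9
Lilra4	LILRA4
Lmo2	LMO2
Lsp1	LSP1
Lta	LTA
Lta4h	LTA4H
Ltb	LTB
Ltc4s	LTC4S
Ltf	LTF
Lum	LUM
Ly6e	LY6E
Lyn	LYN
Lyve1	LYVE1
Lyz2	LYZ
Madcam1	MADCAM1
Maf	MAF
Mafb	MAFB
Mcl1	MCL1
Mcpt4	CMA1
Mecom	MECOM
Meis1	MEIS1
Mertk	MERTK
Mki67	MKI67
Mmp2	MMP2
Mmp8	MMP8
Mmp9	MMP9
Mpl	MPL
Mpo	MPO
Mrc1	MRC1
Ms4a1	MS4A1
Ms4a2	MS4A2
Ms4a6a	MS4A6A
Ms4a7	MS4A7
Msr1	MSR1
Muc1	MUC1
Mx1	MX1
Mx2	MX2
Myd88	MYD88
Myh11	MYH11
Mzb1	MZB1
Ncf1	NCF1
Ncf2	NCF2
Ncf4	NCF4
Ncr1	NCR1
Ncr3	NCR3
Neurod1	NEUROD1
Nfil3	NFIL3
Nfkb1	NFKB1
Nfkb2	NFKB2
Nkg7	NKG7
Nkx6-1	NKX6-1
Nlrp3	NLRP3
Nod2	NOD2
Nos2	NOS2
Notch3	NOTCH3
Nr4a1	NR4A1
Nrp1	NRP1
Nt5e	NT5E
Oas1	OAS1
Oas3	OAS3
Pax5	PAX5
Pcna	PCNA
Pcsk1	PCSK1
Pcsk2	PCSK2
Pdcd1	PDCD1
Pdcd1lg2	PDCD1LG2
Pdgfb	PDGFB
Pdgfra	PDGFRA
Pdgfrb	PDGFRB
Pdpn	PDPN
Pdx1	PDX1
Pecam1	PECAM1
Pecam1b	PECAM1B
Pf4	PF4
Pigr	PIGR
Plcg2	PLCG2
Plek	PLEK
Postn	POSTN
Pou2af1	POU2AF1
Ppbp	PPBP
Ppy	PPY
Prdm1	PRDM1
Prdm16	PRDM16
Prf1	PRF1
Prg2	PRG2
Prox1	PROX1
Prtn3	PRTN3
Psgl1	PSGL1
Psmb8	PSMB8
Psmb9	PSMB9
Ptgdr2	PTGDR2
Ptgs2	PTGS2
Ptprc	PTPRC
Ptprcap	PTPRCAP
Pycard	PYCARD
Rac2	RAC2
Ramp2	RAMP2
Rel	REL
Rela	RELA
Relb	RELB
Rgs5	RGS5
Rhag	RHAG
Rnase2	RNASE2
Rnase3	RNASE3
Robo4	ROBO4
Rora	RORA
Rorc	RORC
Rsad2	RSAD2
Runx1	RUNX1
Runx1b	RUNX1B
Runx3	RUNX3
S100a12	S100A12
S100a8	S100A8
S100a9	S100A9
Sash3	SASH3
Scg2	SCG2
Sdc1	SDC1
Sele	SELE
Sell	SELL
Sell3	SELL3
Selp	SELP
Selplg	SELPLG
Serping1	SERPING1
Sfn	SFN
Sh2d1a	SH2D1A
Siglec1	SIGLEC1
Siglec8	SIGLEC8
Sirpa	SIRPA
Slamf1	SLAMF1
Slamf6	SLAMF6
Slamf7	SLAMF7
Slc4a1	SLC4A1
Socs1	SOCS1
Socs3	SOCS3
Sox18	SOX18
Sparc	SPARC
Spi1	SPI1
Spib	SPIB
Sst	SST
Stab1	STAB1
Stat1	STAT1
Stat2	STAT2
Stat3	STAT3
Stat4	STAT4
Stat5a	STAT5A
Stat5b	STAT5B
Stat6	STAT6
Syk	SYK
Tagln	TAGLN
Tal1	TAL1
Tap1	TAP1
Tap2	TAP2
Tbx21	TBX21
Tcf4	TCF4
Tcf7	TCF7
Tdo2	TDO2
Tek	TEK
Tf	TF
Tgfb1	TGFB1
Tgfb2	TGFB2
Tgfb3	TGFB3
Thy1	THY1
Thy2	THY2
Ticam1	TICAM1
Tie1	TIE1
Tigit	TIGIT
Tlr1	TLR1
Tlr2	TLR2
Tlr3	TLR3
Tlr4	TLR4
Tlr5	TLR5
Tlr6	TLR6
Tlr7	TLR7
Tlr8	TLR8
Tlr9	TLR9
Tnf	TNF
Tnfrsf13b	TNFRSF13B
Tnfrsf13c	TNFRSF13C
Tnfrsf14	TNFRSF14
Tnfrsf17	TNFRSF17
Tnfrsf1a	TNFRSF1A
Tnfrsf1b	TNFRSF1B
Tnfrsf4	TNFRSF4
Tnfrsf9	TNFRSF9
Tnfsf10	TNFSF10
Tnfsf13b	TNFSF13B
Tnfsf14	TNFSF14
Tnfsf9	TNFSF9
Top2a	TOP2A
Tox	TOX
Tpsab1	TPSAB1
Tpsb2	TPSB2
Traf3ip3	TRAF3IP3
Trem2	TREM2
Ttr	TTR
Tubb1	TUBB1
Tyk2	TYK2
Tyrobp	TYROBP
Ube2c	UBE2C
Vcam1	VCAM1
Vcan	VCAN
Vim	VIM
Vpreb3	VPREB3
Vsir	VSIR
Vwf	VWF
Was	WAS
Xbp1	XBP1
Xcl1	XCL1
Xcr1	XCR1
Zap70	ZAP70
Zbtb46	ZBTB46
Zeb2	ZEB2
Znf683	ZNF683
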