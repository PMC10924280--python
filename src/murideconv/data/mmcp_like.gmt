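T cells	curated murine markers	Cd3e	Cd3d	Cd3g	Cd2	Lck	Thy1	Cd5
CD8 T cells	curated murine markers	Cd8a	Cd8b1	Gzmk
NK cells	curated murine markers	Ncr1	Klrb1c	Eomes	Prf1	Klrk1
B cells	curated murine markers	Cd19	Ms4a1	Cd79a	Cd79b	Pax5
Memory B cells	curated murine markers	Cd27	Cd38	Cd80	Cd40
Plasma cells	curated murine markers	Sdc1	Xbp1	Prdm1	Jchain	Mzb1
Monocytes	curated murine markers	Ccr2	Cd14	Fcn1	Vcan
Macrophages	curated murine markers	Adgre1	Mrc1	Cd68	Csf1r	Mertk	C1qa
Dendritic cells	curated murine markers	Itgax	Flt3	Zbtb46	Batf3	Xcr1
Mast cells	curated murine markers	Kit	Cpa3	Mcpt4	Ms4a2	Hdc
Eosinophils	curated murine markers	Prg2	Epx	Il5ra	Ccr3
Neutrophils	curated murine markers	S100a8	S100a9	Mpo	Elane	Csf3r	Cxcr2
Endothelial cells	curated murine markers	Pecam1	Cdh5	Vwf	Kdr	Tek	Cldn5
Fibroblasts	curated murine markers	Col1a1	Col1a2	Pdgfra	Dcn	Lum	Postn
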