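TDS_16	thyroid differentiation genes (editable default)	DIO1	DIO2	DUOX1	DUOX2	FOXE1	GLIS3	NKX2-1	PAX8	SLC26A4	SLC5A5	SLC5A8	TG	THRA	THRB	TPO	TSHR
IMMUNE	66 immune cell-surface markers and immune regulation genes (synthetic placeholder default, replace with your curated list)	CD2	CD3D	CD3E	CD3G	CD4	CD8A	CD8B	CD19	MS4A1	CD27	CD28	CD38	CD40	CD40LG	CD48	CD52	CD69	CD80	CD86	CD163	CD14	FCGR3A	NCAM1	KLRD1	KLRK1	NKG7	GZMA	GZMB	GZMH	GZMK	PRF1	IFNG	TNF	IL2	IL2RA	IL2RB	IL7R	IL10	IL15	TGFB1	FOXP3	CTLA4	PDCD1	CD274	PDCD1LG2	LAG3	HAVCR2	TIGIT	BTLA	ICOS	TNFRSF4	TNFRSF9	TNFRSF18	CXCR3	CXCR6	CCR7	CCL5	CXCL9	CXCL10	CXCL13	CCL19	HLA-DRA	HLA-DRB1	HLA-A	TAP1	B2M
STROMAL	stromal / extracellular-matrix enrichment set (synthetic placeholder default)	COL1A1	COL1A2	COL3A1	COL5A1	COL5A2	COL6A1	COL6A2	COL6A3	FN1	FBN1	LUM	DCN	POSTN	THBS1	THBS2	SPARC	FAP	PDGFRA	PDGFRB	ACTA2	TAGLN	MMP2	MMP14	VCAN	FBLN1	COL4A1	LAMA4	SERPINF1	OGN	AEBP1
GEP	18-gene T-cell-inflamed gene expression profile (editable default)	CCL5	CD27	CD274	CD276	CD8A	CMKLR1	CXCL9	CXCR6	HLA-DQA1	HLA-DRB1	HLA-E	IDO1	LAG3	NKG7	PDCD1LG2	PSMB10	STAT1	TIGIT
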