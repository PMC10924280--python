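method	raw	canonical
mmcp_like	T cells	T cell
mmcp_like	CD8 T cells	T cell CD8+
mmcp_like	NK cells	NK cell
mmcp_like	B cells	B cell
mmcp_like	Memory B cells	B cell memory
mmcp_like	Plasma cells	Plasma cell
mmcp_like	Monocytes	Monocyte
mmcp_like	Macrophages	Macrophage
mmcp_like	Dendritic cells	Dendritic cell myeloid
mmcp_like	Mast cells	Mast cell
mmcp_like	Eosinophils	Eosinophil
mmcp_like	Neutrophils	Neutrophil
mmcp_like	Endothelial cells	Endothelial cell
mmcp_like	Fibroblasts	Fibroblast
seqimmucc_like	B cells	B cell
seqimmucc_like	CD4 T cells	T cell CD4+
seqimmucc_like	CD8 T cells	T cell CD8+
seqimmucc_like	NK cells	NK cell
seqimmucc_like	Monocytes	Monocyte
seqimmucc_like	Macrophages	Macrophage
seqimmucc_like	Dendritic cells	Dendritic cell myeloid
seqimmucc_like	Neutrophils	Neutrophil
seqimmucc_like	Eosinophils	Eosinophil
seqimmucc_like	Mast cells	Mast cell
base_like	CD8 T	T cell CD8+
base_like	CD4 T	T cell CD4+
base_like	NK	NK cell
base_like	B	B cell
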