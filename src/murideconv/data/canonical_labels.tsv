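canonical	definition
B cell	CD19+ B lymphocyte
B cell memory	controlled vocabulary label
Basophil	basophil granulocyte
Dendritic cell myeloid	conventional/myeloid dendritic cell
Dendritic cell plasmacytoid	plasmacytoid dendritic cell
Endothelial cell	controlled vocabulary label
Eosinophil	eosinophil granulocyte
Fibroblast	controlled vocabulary label
Hematopoietic progenitor	CD34+/Kit+ progenitor
Innate lymphoid cell	non-NK innate lymphoid cell (ILC1/2/3)
Macrophage	tissue macrophage
Mast cell	tissue mast cell
Megakaryocyte	platelet-producing megakaryocyte
Monocyte	circulating classical/non-classical monocyte
NK cell	natural killer cell
Neutrophil	polymorphonuclear neutrophil
Plasma cell	antibody-secreting B-lineage cell
T cell	controlled vocabulary label
T cell CD4+	conventional CD4+ alpha-beta T cell
T cell CD8+	cytotoxic CD8+ alpha-beta T cell
T cell NKT	invariant natural killer T cell
T cell gamma delta	gamma-delta T cell
T cell regulatory	Foxp3+ regulatory T cell
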