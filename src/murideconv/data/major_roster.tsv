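major	definition
T cell CD4+	conventional CD4+ alpha-beta T cell
T cell CD8+	cytotoxic CD8+ alpha-beta T cell
T cell gamma delta	gamma-delta T cell
T cell regulatory	Foxp3+ regulatory T cell
T cell NKT	invariant natural killer T cell
B cell	CD19+ B lymphocyte
Plasma cell	antibody-secreting B-lineage cell
NK cell	natural killer cell
Monocyte	circulating classical/non-classical monocyte
Macrophage	tissue macrophage
Dendritic cell myeloid	conventional/myeloid dendritic cell
Dendritic cell plasmacytoid	plasmacytoid dendritic cell
Neutrophil	polymorphonuclear neutrophil
Eosinophil	eosinophil granulocyte
Basophil	basophil granulocyte
Mast cell	tissue mast cell
Innate lymphoid cell	non-NK innate lymphoid cell (ILC1/2/3)
Hematopoietic progenitor	CD34+/Kit+ progenitor
Megakaryocyte	platelet-producing megakaryocyte
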