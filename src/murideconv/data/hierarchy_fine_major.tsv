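fine	major
T cell CD4+ naive	T cell CD4+
T cell CD4+ memory	T cell CD4+
T cell CD4+ effector	T cell CD4+
T cell CD4+ activated	T cell CD4+
T cell CD4+ resting	T cell CD4+
T cell CD4+ exhausted	T cell CD4+
T cell CD4+ cycling	T cell CD4+
T cell CD4+ tissue-resident	T cell CD4+
T cell CD4+ IFN-stimulated	T cell CD4+
T cell CD4+ regulatory phenotype	T cell CD4+
T cell CD8+ naive	T cell CD8+
T cell CD8+ memory	T cell CD8+
T cell CD8+ effector	T cell CD8+
T cell CD8+ activated	T cell CD8+
T cell CD8+ resting	T cell CD8+
T cell CD8+ exhausted	T cell CD8+
T cell CD8+ cycling	T cell CD8+
T cell CD8+ tissue-resident	T cell CD8+
T cell CD8+ IFN-stimulated	T cell CD8+
T cell CD8+ regulatory phenotype	T cell CD8+
T cell gamma delta naive	T cell gamma delta
T cell gamma delta memory	T cell gamma delta
T cell gamma delta effector	T cell gamma delta
T cell gamma delta activated	T cell gamma delta
T cell gamma delta resting	T cell gamma delta
T cell gamma delta exhausted	T cell gamma delta
T cell gamma delta cycling	T cell gamma delta
T cell gamma delta tissue-resident	T cell gamma delta
T cell gamma delta IFN-stimulated	T cell gamma delta
T cell gamma delta regulatory phenotype	T cell gamma delta
T cell regulatory naive	T cell regulatory
T cell regulatory memory	T cell regulatory
T cell regulatory effector	T cell regulatory
T cell regulatory activated	T cell regulatory
T cell regulatory resting	T cell regulatory
T cell regulatory exhausted	T cell regulatory
T cell regulatory cycling	T cell regulatory
T cell regulatory tissue-resident	T cell regulatory
T cell regulatory IFN-stimulated	T cell regulatory
T cell regulatory regulatory phenotype	T cell regulatory
T cell NKT naive	T cell NKT
T cell NKT memory	T cell NKT
T cell NKT effector	T cell NKT
T cell NKT activated	T cell NKT
T cell NKT resting	T cell NKT
T cell NKT exhausted	T cell NKT
T cell NKT cycling	T cell NKT
T cell NKT tissue-resident	T cell NKT
T cell NKT IFN-stimulated	T cell NKT
T cell NKT regulatory phenotype	T cell NKT
B cell naive	B cell
B cell memory	B cell
B cell effector	B cell
B cell activated	B cell
B cell resting	B cell
B cell exhausted	B cell
B cell cycling	B cell
B cell tissue-resident	B cell
B cell IFN-stimulated	B cell
B cell regulatory phenotype	B cell
Plasma cell naive	Plasma cell
Plasma cell memory	Plasma cell
Plasma cell effector	Plasma cell
Plasma cell activated	Plasma cell
Plasma cell resting	Plasma cell
Plasma cell exhausted	Plasma cell
Plasma cell cycling	Plasma cell
Plasma cell tissue-resident	Plasma cell
Plasma cell IFN-stimulated	Plasma cell
Plasma cell regulatory phenotype	Plasma cell
NK cell naive	NK cell
NK cell memory	NK cell
NK cell effector	NK cell
NK cell activated	NK cell
NK cell resting	NK cell
NK cell exhausted	NK cell
NK cell cycling	NK cell
NK cell tissue-resident	NK cell
NK cell IFN-stimulated	NK cell
NK cell regulatory phenotype	NK cell
Monocyte naive	Monocyte
Monocyte memory	Monocyte
Monocyte effector	Monocyte
Monocyte activated	Monocyte
Monocyte resting	Monocyte
Monocyte exhausted	Monocyte
Monocyte cycling	Monocyte
Monocyte tissue-resident	Monocyte
Monocyte IFN-stimulated	Monocyte
Monocyte regulatory phenotype	Monocyte
Macrophage naive	Macrophage
Macrophage memory	Macrophage
Macrophage effector	Macrophage
Macrophage activated	Macrophage
Macrophage resting	Macrophage
Macrophage exhausted	Macrophage
Macrophage cycling	Macrophage
Macrophage tissue-resident	Macrophage
Macrophage IFN-stimulated	Macrophage
Macrophage regulatory phenotype	Macrophage
Dendritic cell myeloid naive	Dendritic cell myeloid
Dendritic cell myeloid memory	Dendritic cell myeloid
Dendritic cell myeloid effector	Dendritic cell myeloid
Dendritic cell myeloid activated	Dendritic cell myeloid
Dendritic cell myeloid resting	Dendritic cell myeloid
Dendritic cell myeloid exhausted	Dendritic cell myeloid
Dendritic cell myeloid cycling	Dendritic cell myeloid
Dendritic cell myeloid tissue-resident	Dendritic cell myeloid
Dendritic cell myeloid IFN-stimulated	Dendritic cell myeloid
Dendritic cell myeloid regulatory phenotype	Dendritic cell myeloid
Dendritic cell plasmacytoid naive	Dendritic cell plasmacytoid
Dendritic cell plasmacytoid memory	Dendritic cell plasmacytoid
Dendritic cell plasmacytoid effector	Dendritic cell plasmacytoid
Dendritic cell plasmacytoid activated	Dendritic cell plasmacytoid
Dendritic cell plasmacytoid resting	Dendritic cell plasmacytoid
Dendritic cell plasmacytoid exhausted	Dendritic cell plasmacytoid
Dendritic cell plasmacytoid cycling	Dendritic cell plasmacytoid
Dendritic cell plasmacytoid tissue-resident	Dendritic cell plasmacytoid
Dendritic cell plasmacytoid IFN-stimulated	Dendritic cell plasmacytoid
Dendritic cell plasmacytoid regulatory phenotype	Dendritic cell plasmacytoid
Neutrophil naive	Neutrophil
Neutrophil memory	Neutrophil
Neutrophil effector	Neutrophil
Neutrophil activated	Neutrophil
Neutrophil resting	Neutrophil
Neutrophil exhausted	Neutrophil
Neutrophil cycling	Neutrophil
Neutrophil tissue-resident	Neutrophil
Neutrophil IFN-stimulated	Neutrophil
Neutrophil regulatory phenotype	Neutrophil
Eosinophil naive	Eosinophil
Eosinophil memory	Eosinophil
Eosinophil effector	Eosinophil
Eosinophil activated	Eosinophil
Eosinophil resting	Eosinophil
Eosinophil exhausted	Eosinophil
Eosinophil cycling	Eosinophil
Eosinophil tissue-resident	Eosinophil
Eosinophil IFN-stimulated	Eosinophil
Eosinophil regulatory phenotype	Eosinophil
Basophil naive	Basophil
Basophil memory	Basophil
Basophil effector	Basophil
Basophil activated	Basophil
Basophil resting	Basophil
Basophil exhausted	Basophil
Basophil cycling	Basophil
Basophil tissue-resident	Basophil
Basophil IFN-stimulated	Basophil
Basophil regulatory phenotype	Basophil
Mast cell naive	Mast cell
Mast cell memory	Mast cell
Mast cell effector	Mast cell
Mast cell activated	Mast cell
Mast cell resting	Mast cell
Mast cell exhausted	Mast cell
Mast cell cycling	Mast cell
Mast cell tissue-resident	Mast cell
Mast cell IFN-stimulated	Mast cell
Mast cell regulatory phenotype	Mast cell
Innate lymphoid cell naive	Innate lymphoid cell
Innate lymphoid cell memory	Innate lymphoid cell
Innate lymphoid cell effector	Innate lymphoid cell
Innate lymphoid cell activated	Innate lymphoid cell
Innate lymphoid cell resting	Innate lymphoid cell
Innate lymphoid cell exhausted	Innate lymphoid cell
Innate lymphoid cell cycling	Innate lymphoid cell
Innate lymphoid cell tissue-resident	Innate lymphoid cell
Innate lymphoid cell IFN-stimulated	Innate lymphoid cell
Innate lymphoid cell regulatory phenotype	Innate lymphoid cell
Hematopoietic progenitor naive	Hematopoietic progenitor
Hematopoietic progenitor memory	Hematopoietic progenitor
Hematopoietic progenitor effector	Hematopoietic progenitor
Hematopoietic progenitor activated	Hematopoietic progenitor
Hematopoietic progenitor resting	Hematopoietic progenitor
Hematopoietic progenitor exhausted	Hematopoietic progenitor
Hematopoietic progenitor cycling	Hematopoietic progenitor
Hematopoietic progenitor tissue-resident	Hematopoietic progenitor
Hematopoietic progenitor IFN-stimulated	Hematopoietic progenitor
Hematopoietic progenitor regulatory phenotype	Hematopoietic progenitor
Megakaryocyte naive	Megakaryocyte
Megakaryocyte memory	Megakaryocyte
Megakaryocyte effector	Megakaryocyte
Megakaryocyte activated	Megakaryocyte
Megakaryocyte resting	Megakaryocyte
Megakaryocyte exhausted	Megakaryocyte
Megakaryocyte cycling	Megakaryocyte
Megakaryocyte tissue-resident	Megakaryocyte
Megakaryocyte IFN-stimulated	Megakaryocyte
Megakaryocyte regulatory phenotype	Megakaryocyte
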