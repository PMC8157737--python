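protein_id,organism,role,mark
Prmt5,mouse,writer,methylation
Ezh2,mouse,writer,methylation
Setd2,mouse,writer,methylation
Suv39h1,mouse,writer,methylation
Kdm1a,mouse,eraser,methylation
Kdm6b,mouse,eraser,methylation
Kat2a,mouse,writer,acetylation
Ep300,mouse,writer,acetylation
Hdac1,mouse,eraser,acetylation
Hdac2,mouse,eraser,acetylation
Sirt1,mouse,eraser,acetylation
Brd4,mouse,reader,acetylation
Cbx5,mouse,reader,methylation
Cbx7,mouse,reader,methylation
EZH2,human,writer,methylation
HDAC1,human,eraser,acetylation
BRD4,human,reader,acetylation
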