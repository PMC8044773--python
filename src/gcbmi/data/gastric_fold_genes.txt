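# Per-fold biomarker gene lists from a published gastric tumor/normal
# multi-omics integration (5-fold cross-validation; DEG ∩ DMP per fold).
# Format: fold index <TAB> comma-separated gene symbols.
1	FAHD2A,PGC,FIGF,PPAP2B,FOXA1,IFITM2,HOXC10,GPRC5C,CLEC3B,FBN1,LIF,C5,PSCA,PDGFD,KCNE2,RORC,C3
2	PGC,FIGF,NID2,PPAP2B,IFITM2,RAB31,RORC,GPRC5C,FSCN1,TEAD4,CLEC3B,RAB17,IGFALS,C5,PSCA,PDGFD,KCNE2,COL4A1,C3
3	FAHD2A,PGC,PPAP2B,FOXA1,IFITM2,IGFALS,GPRC5C,TEAD4,DNM1,ORM1,PTPRN2,FBN1,PSCA,PDGFD,KCNE2,RORC,C3
4	PGC,FIGF,PDGFRB,PSMA7,TEAD4,C5,RORC,ADA,IFITM1,FAHD2A,PPAP2B,IGFALS,SLC1A2,GPRC5C,CLEC3B,CAPN9,KCNE2,PSCA,IFITM2,FSCN1,RPRM,PDGFD,SERPINA4,FBN1
5	IFITM1,PGC,FIGF,PPAP2B,KCNE2,IFITM2,HOXC10,GPRC5C,CAPN9,FBN1,HRAS,C5,PSCA,PDGFD,SERPINA4,RORC,C3
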