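sample_id,rna_chain,rna_v,rna_j,rna_pct,rna_productive,dna_v,dna_d,dna_j,dna_pct,dna_productive,dna_failure,common_cdr3_aa
PLC-01,IGH,IGHV3-48,IGHJ4,92.90,true,IGHV3-30*09,,IGHJ4*02,67.55,true,,CARDSYEDYVYW
PLC-02,IGH,IGHV3-21,IGHJ4,97.93,true,IGHV3-21*01,,IGHJ4*02,74.39,true,,CARYQLDAVAGKWGHYFDYW
PLC-03,IGH,IGHV3-43,IGHJ5,97.77,true,IGHV3-9*01,,IGHJ4*02,66.23,true,,CAKARLPLVGGLDSW
PLC-05,IGH,IGHV3-43,IGHJ6,49.79,true,IGHV3-9*01,,IGHJ6*02,13.62,true,,CTRVIGSGASCYDCYYHGMDVW
PLC-06,IGH,IGHV3-53,IGHJ5,87.91,true,IGHV3-53*01,,IGHJ4*02,57.58,true,,CARGLTAPGFPLDSW
PLC-07,IGH,IGHV3-23,IGHJ6,65.26,true,IGHV3-23*01,,IGHJ6*01,56.92,true,,CAKGRADCTDGVCYRRYGMDVW
PLC-08,IGH,IGHV3-43,IGHJ4,99.44,true,IGHV3-43*01,,IGHJ4*02,81.44,true,,CVKGQGGYTYGGFDCW
PLC-10,IGH,IGHV5-51,IGHJ4,77.63,true,IGHV5-51*01,,IGHJ4*02,57.39,true,,CARTNWPYYFDHW
PLC-12,IGH,IGHV3-43,IGHJ4,93.73,true,IGHV3-9*01,,IGHJ4*02,62.86,true,,CARDRYQLIIYYFDRW
PLC-14,IGH,IGHV1-18,IGHJ4,98.08,true,IGHV3-23*01,IGHD3-9*01,IGHJ5*02,78.00,false,stop_codon,
PLC-15,IGH,IGHV3-43,IGHJ4,98.97,true,IGHV3-9*01,,IGHJ4*02,32.77,true,,CAKDVRYGYGSTQSAGFDYW
PLC-16,IGK,IGKV1-33,IGKJ3,79.00,true,IGHV3-11*05,IGHD3-3*01,IGHJ5*02,29.97,false,,
PLC-17,IGH,IGHV4-39,IGHJ4,95.53,true,IGHV4-39*07,,IGHJ4*02,22.10,true,,CARDKTTMTFSSPIFDYW
PLC-18,IGH,IGHV2-5,IGHJ1,95.78,true,IGHV2-5*02,,IGHJ1*01,56.58,true,,CAHSGSMWSGYAGTEYFQHW
PLC-19,IGH,IGHV4-59,IGHJ4,67.50,true,IGHV4-59*01,,IGHJ4*02,21.08,true,,CARAGDYDLLLLDYW
PLC-21,IGH,IGHV5-51,IGHJ6,80.02,true,IGHV5-51*03,,IGHJ6*03,56.06,true,,CARLPQGGYYYMDVW
PLC-22,IGH,IGHV3-53,IGHJ5,85.10,true,IGHV3-53*01,,IGHJ4*02,77.01,true,,CARGLTAPGFPLDSW
PLC-23,IGH,IGHV3-33,IGHJ1,56.11,true,IGHV3-30-3*02,,IGHJ1*01,61.13,true,,CAFAIGADGEYFQHW
PLC-24,IGH,IGHV2-70,IGHJ4,69.68,true,IGHV2-70*01,,IGHJ4*02,40.67,true,,CARGASETQVAMSTAELYFFDSW
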