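>IGHD2-2|*01|IGH|D|-|0
GGACGGCCGTGGTCAT
>IGHD3-3|*01|IGH|D|-|0
TCCATCGGCTTTCGTATTCC
>IGHD3-9|*01|IGH|D|-|0
CCGAAGGGAATGTAGCCCTGAATT
>IGHJ4|*01|IGH|J|12|0
GCCTACTCAACTTGGCTACGTCGCTCCACAGGGGAAAAGGCTCGGGTA
>IGHJ5|*01|IGH|J|12|0
CAAATCCTACTGTGGCGACCCGCCGCGGCTCCTAAAAAGGCTCGGGTA
>IGHJ6|*01|IGH|J|12|0
ATGACCAGAGAATGGAAACCGTGTTCGACGGGGCAAAAGGCTCGGGTA
>IGHV1-18|*01|IGH|V|288|0
CATCAGCACAGTGTGACTAAATTGGCACTCAAAAGTGGGATACAATGTCACAGCCACTTA
GCCTTGCAGTTCTCCATGCCTGCAAACTTACGAGCACCGAAGGATCCTAACCCCAAAGAG
ATTCTATCCCCATTTCACCTGACGCTCGATCAACTGCCAGATAAGGGAATGATGTACGGT
CGAGGAGAGGACGGCACCTGTTTCCTGTACCCTAGCATGGACCGCAGTTTCGGACGAAAC
GCGTTGGAAAGGATTTGCCCGTCTAGCATAACTTTGCGTAGCTCGTCCTGCACCGC
>IGHV3-23|*01|IGH|V|288|0
GAATTAAGATCTCTGGTTAAGATGGTCGCGGTTGTGCGAACCGATCCCTATCGAATTAGG
CACAGTCCCACTCCAGGCATGTCACAAGTGACCATCAGAGGTCATGCCGAATCTAAGGCT
CTAGGGCGGACATTTCAGTGTTTGTTAGAGGAGCATATTCAGGCACGGGTATATACGCCT
CCGCTAAATACGGCGGGCTTCCTGAATGGTGTAGCGCGTCCCTTATCGACTGAGCGGTAT
AGCATTAGTTTTAATCGCAGTAAAGGAACGCACGACTTGCTTGTAGCCTGCCCAAC
>IGHV3-43|*01|IGH|V|288|0
AGCGGGCCAGATCCCCCCTGGGCTGAAACCTCGAATATAGTCGCCCTAGGGCAAACGCAG
CACAGTCCCACTCCAGGCATTCCATCTTTCTGTAGTGTAACATTTAGCGTATCGTATTTT
TATCCTCTTGCGCCGATGGTTGTATCCTCTCAAGGAAATTACGATAGACAACGACCTTGT
TCTCATATCCGAGTAGTTAGATGCTATTATGCTGTAATACGAGCTTACGGACAAGTAAAC
TTATCCCGTTGTGCCGCGGTAGCGACTCTGATGTGGTTACTCTACCTGTGTTGCAG
>IGHV3-9|*01|IGH|V|288|0
AGCGGGCCAGATGCCCCCTGGGCTGAAACCTCTAATATAGTCGCCCTAGGGCAAACGCAG
CACAGTCCCACTCCAGGCATTGCATCTTTCTGTACTGTAACACTTAGCGTATCGTATTTT
TATCCTCTTGCGCCGATTGTGGTATCCTCTCAAGGAAATCACGATGCTCAACGACCTTGT
TCTCATATACGAGTAGTTACATGCTATTTTGCTGCAATAAGAGCTTTCGGACATTTAAAT
CTATGCTGTTGTGCACCGGTGGAGACTCTGGTGTGGTTACACTACCTGTGTTGCAG
>IGHV4-39|*01|IGH|V|288|0
ACGTGCAGACTCAGTGTACCAACTGTGCACGCCCTAGCTTATTCGCCTGAGCTTTTTGGG
GAAAATGCGTCTTCCAATGGCCGGCACGCTGCCAGGGATTCGTTTCTTCGACAAGTCAAC
ATGCTTCTATTTACGATGACAAGTATCGATACTTTTCTTGGTGCCATGTCACGCATTACC
GCGCGCCGCACAGTCTCGGATGCGTCGGAACCCTGCTGCGGCGCCGTAGGTGGCCTGAGA
CCCTCGACGAGCCAACCGAAAATGAGAAGCCACGACACCATTATTCTATGCAAGCG
>IGHV5-51|*01|IGH|V|288|0
CACAAGCCAGCATCAATATCTCTTGCTCTCTTCCCTGGAGTCCTATTTCCTCTTATCAGG
CTTTGGGCCAGTAATGTGGCGTTTAAAACTATAGGATTGGCTGTCCTACTCGGAGGAAGT
ATGGCCCAAACCATAGACTTTTGGGCGTCGTTGACTGAATCACCCTGCGACAATCGGGCC
CCACATAACGCCACGAGTCGAGTTGGATCAGGCGGCGTGGGTAAGTATATGTCGTTAGCG
CACCTGCTTAGATCTGTGCGCGTCCTGACCATGACCGGACTACTCACTTGTTACCC
>IGKJ1|*01|IGK|J|9|0
CCAGTTACATTCCATGCTAAAGGATTCCTTACATGCCTAAACTCT
>IGKJ3|*01|IGK|J|9|0
CCTCTCGCATTTGGGAGATCTAGCCCAAAGTGCAGTCTGATCATT
>IGKV1-33|*01|IGK|V|282|0
TACGATACCGCCTGTGCAATCTCTATATCAGGATCTCCTAGGACTCGGAAGAAGGTCCCT
GTGGCTCAAAGGTCTAAGCCGCCATGGATGACCGCCCTAATCTACTTAGCAGCTGCTGGA
AGAAATCAGCTATATGGAACGACCAGGGGGCGTGTCAGCTGTATGACTGGTAGATTCTAT
AATGTGCGAGTCATTGACAGTATATACGATGGACCCTCTAAGACCCCGAGAAGGCGTACC
TACGGGTTTCTTGCATTTGTAAGCCACCATTTAGTCCAAGCTTGCCGGAG
>IGKV3-20|*01|IGK|V|282|0
CGATCATGCCGTTATTCGTTTACCGGGTTGTTCTCGGCTTTTTCGCAGTACCTTCAAAAG
GTGGCTCAAAGGTCTAAGCCAGAGTTATGGATTCCTCGTCCCAATACATATCATGCCAGA
CAGTTTCTCTCGACCCTAGTAGCAGTGCTGGTACGTAGCTTTATCGGAGAGCACACCAAA
CGCGCGGTTCACACTAGTGGCACCAAGACCACTGGAGGCAAATATCACCTCATGATTGAG
GGTGTTGGAAGATACGGCGAAGCTGCATATGAACAGAACCGTTGTGGCGT
>IGKV4-1|*01|IGK|V|282|0
GGCATATGTTTACACAACTGCTGCGACAGAGAAATGTGTAGTGCTTACCAAGTGAGGAGG
GTGGCTCAAAGGTCTAAGCCCCTGTTAGATTGTGGCATTCCCTGTATCTGCTTATCGTTA
AGATCTTACGACTTCCCGTCATACCGCCCCCACAGGGGCCTCATTCAGATGGGCATTTTC
AATAGATCGGGGGGAGAAGGAGATGCACGGGACGCCAATCACCAATCTGCTAACGCACAC
TGTCTTTGCTACCAACCAAACATCCCGCGTGCAGGAAGAGAGTGTCAAGG
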