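>AR_LBD_synthetic synthetic illustrative AR ligand-binding-domain region
GTTACTATTCCAACGGTTGTAAGAAGCTGGCAAAGACATAATGTGTAGGTCGACCATCTGGGGACACATA
GCTGATTTGAATGATGGCCAATCGCTACAATGCGTCGGCGTTATATTACTAGTGTAACACTGCATCTGGT
TGCTCTACGTATGGGTCCAAATTAGCGGCTCGGAACTTTATTTGTAAAAAAGAGAGACTGTGGAGATTTA
CCAGTCTTATTAGGGAGGTTCTTTAAGAGTCACGACAGTCCGAACCATGCATAAAATACTGACTCGATTT
GCAGTAAGTTAATGTTTTTCCTCTTCCCATGCGTCTTCATTAGTTAATAAGCTATATACACCGCATTTAC
AAAGAATCAGAGCGGGCTTAAATTATAGCTACGAACTTTTGTGTCATATGCTAGATGTCTGGTCCGTCGA
GTATATCCTGTAGGTACGGAGAATACTGGTCGTGGCGCTCCTGCTCTTCGACTGGGGGCACCCTCCCGTT
CATCGATCCACTTCTCCGACGTATTCAGAGCGACGGATCCAACTGAACTCTGGTTCACCACGAAACTAAA
CACAATAGCCTATTGAGGTATTACATTTGGGGTGCGATGCTTCAAACCTATGTCATAATGAATAGATAGA
GTAATGCGCTCTGTCTGCATGATACTCCCAAAAACATTAGGAATCTAGTTAGCTAATCCTCACAAGTGGC
TGGTGAGCAGTAGTCACGGGATTAAATTACACTAACGTCACTTATCTATACGGAACAAACCGCACTACTC
TTCTAACGTAGCATGATAACTATGAGCGTGTATCTTTACTTCTCCTCCCCAATGGTAAACTCCGAAGTCG
ACGACGGAGATAAATCGTTAGGGCCAAGAACAATCAGAATTGACAAAAGAATCCATGGGAAGTTGGATAA
GTTCAATTATCCGACAGGTTCCTGAATGAGGCTTAACTGTGATAGACTGACGAAAGCGCGATTCCTCTCG
CGTATGCCAAGAGTTTTATATTGGAGCAATTAAAAAGCCAGCCCTAGCTCGTGAATACTAAAACGCATTG
AGGCTCGAGTTATGCCTAGGGTCCCTCGCTTATGACAGACCGTTCGACTATGCTCTAATCAGCGTTAGTC
TATGTTTAGAACGGTAACTGGTGCACTGACCGGTCCGTGCTCTCATCTGGATATTCATCACACGTTACCT
AGTCAGCTAAAGCTTTAACTTAGTTGTTCATACTGGTCTTCCATAATGGTAACAGTGGAATAGATACGGT
TCAGTATACGGTGCGCCCCCAACCTTCGTCGCGCATAGCTTCACTAATTGCGAGGGCATCAAAAATTATA
GCCCGGGGCGCACACACAAGTCAGATACCACAGTCTAGCCTTACTTGTTTGACGTCCAGCTAGGCACTAA
CATTTTGATTTGTCGGCCACCCTGGTAGACTATTGTCCGACCTCATATTGCAAACCTGTTAGAATCAAGC
AGATCGCGTTACAAAATTTGCCCCCTAACGGTAACCTTGACTTGCCGTCAAATGTACTGACGGCATCGGA
AAAACCCTAATGCAGATTCATCGTTTCTCACCTTAACCTTTTGACATAACCTAATTGGATTGAACCACCC
CCCGCATGCGTTTGTAGAAACAGTTAGTAAACAGCGGGAGTTATGACGGAACTCACAATCGCATTACCAG
TTGAAGGCCTAACTAACGAT
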