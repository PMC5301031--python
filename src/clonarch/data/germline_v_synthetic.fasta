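>IGHV1-2 synthetic germline V segment (not an IMGT sequence)
ATTTTGATCCATCTACGGTGTCCTAAATCGTTGGAGGGTGCTATTCGCGAATGGACCGGT
GTTGATTTTCGGTATCCGGCTAATGATCCGCAGTTTATTTGGGTATAAGGAGTAGATGAG
GATACCAAACCGAGCGTCTATGTACTGGATTCATCGGTACAGTTGTCTCAGTTTACACTA
TTTTGCCGGCTTACGGTTGGACTAGTCGATTCTCAAATGGGCCGATGGATAAACCTCTCA
GTCTTGGCGTAATTGTACGGGAGCCTAGTGGTTATGACTTAGAGACCGATGGGT
>IGHV3-21 synthetic germline V segment (not an IMGT sequence)
GCATCTTGGCTCTAAATCTTCACATCGAAAGCTCGGGTGCAGAGAGGGAAGAATATGAAC
AGTCAGCCATCTTTTCGGGCAAGCCCGGAGGAGTGCTCTGCGGACCTTGGGACCAAACCT
TTGGTGTAATGGGTGATCGCATGGAAGAAAAGCCTTAGCGCAGGCAGAGTAAGAAGCTTG
AGTCGTCGCGAAGCGTCTGTTCAAATGCGTATGTCTCTGCAATAGCTTCGTCCGGAGTCT
GGTTGTGGGACTACTAATATTTATTTCTCGGGTATTAGGCCCCAGCACGAGAAG
>IGHV3-23 synthetic germline V segment (not an IMGT sequence)
ATTTGCTGCCCAGGATCTGAATCGACCCTATGTTGCGAGGGGCGGGTGAGAAGAAACAGA
TACCAGGCTGCGATGAAAACAAGGGCTACTGTGGTGTTCAACCGCCTCACAGGGTGTAAC
AGGTATCAACCGCATGAGGTCTTGTTGGACAGGTTATTCTTAGTGTGTCGAAACTATTGC
TTGGAGGAGAGGGGAGGGACGTTACATAAATCTTACGCTTGAGCTGGAACTTGTAGCCGA
TACCAGACAGGGAGCAGGAGACGGGGTCAAGATTGATTCGCCACGCTGGGGTAG
>IGHV3-30 synthetic germline V segment (not an IMGT sequence)
CTTATACGGTACGGCAAGGTACGGGACGCGAGGCTTACATGGGGGATGCCCAGTGTAAGA
GATCCTGTTGAGAGGGTGACCTGACAACAGACAACTGTTTGTCTATGTAGAGTTTGATCG
AAAAATCGATTGTCAAGGGAGCGTAGATACTGATTGACAGATTAAGATTAAAGTATATTG
CCGTAACTCAAGGGGCATAGGTCCACCGTGCCACCGTACTGTGGGAAAGGGGGAGGTCGT
CGGTTGTTTACGGAGGCGTTAAAAAGAGCATAATGGGTTAGATGTCGGCCACAG
>IGHV4-34 synthetic germline V segment (not an IMGT sequence)
GGATTATTTTTTGCTGGTGCGATGAGCAGTCGCCCAGCATAGGTACGTCAACCGACCGCG
CGATGGACCATGTATCGAGTTTGACGCTCCATTATCGTTAATTGTGGGTCAGGGTAACCC
TCTTCTCGGCGCGCATACTGCTCAACATACGGGGGGGGAAGTGCTATAGTGATAATCAAG
TGTCCTGTTCTATATGTGGTACTCTAATTAAAATTAGCATAAGCCGGTTACGTCTAGCGG
GTAGCGAACGACTATGACAAAGGTTATCTGTGACAACATAGGCTATGTTAAAGT
>IGHV6-1 synthetic germline V segment (not an IMGT sequence)
AGCCTATTGTATAAATCGCTTTTGACGGAATTGTTGTGACCTGGGGACGAAAGAAGAAGC
GCTTAGCCTGAATTGCGCATGCGTATTCAGGAATCCCATGTTATTCTACTCTCTCAAGTT
TAGAAGTTAGTCGACGGGGCGCTCCATTTGTGTCAATTACGATCTCCCCCATCAGAGAGT
CGGCAAACGCTTGCTTTTGCCAACGTCCGCAAATCCCTGGCTGAGGGGTATAAGTGCCTC
ATCGTGACGAATTACCAGGCGCGACCAATGGTGGTGTGGGATTTATGGGCATGC
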