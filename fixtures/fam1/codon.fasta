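>fam1_g1
CAAACCCAGAAACGGGCCACCGGGGATATGAATCGGGGCGGTGGACAAGGAGACCCCGATGAAGGTGCGAAAATAGCCGCCGAGACTCCCTTTCCACCCGGTCTGTCTGTCGTACGTAACGCGTCTGTTTCCATTACGCTTCAACTAGCGGCGATGCGTTTCGGACATTTCCTAAACTTAGATCCTGGGACTCGGGATAATCGCTTAGTTGCGGGGTGCTCCCATCAGGAGGTCGAACGGCCAGTTATGTGGTCATCTGTTGAACTTAAAGACGCTCCATCTCCGTGTAGACCGCGCCAACAACACTTCAACGTACATGTTTCATGCGGGCGTCGGGGATCGACTCCCGTCTCATCGCGTCCTCCAATGACCCGGTGCCAACGCCAGTCGCTGACCATTTGCCACGCAACGATGTGGTGGCTGGTAAGCCTCTCTAGCCATTCAAGGGTACTGCTAATTGGCCATAATGTCCCCCTCCTGAATGCTTGCCGCATGGTTCAGAGCGCTGCCCGTAAGCCCAGAAAAAGGCGATTTAATAACCCGACCGAGTACAAAGTCGTAACACACTTGTCGGCCTTATCAGCACTGCCCCAACTTGGGGATAGCACCTGGCTTGGCATCCGTAATATACAAGCCACTAATGCTGCGTATAATCGGGAGAAACTCGACTTGGCCATCGAGGAACCAGTGTCTCCGCGAGCCAATTCCAACAGGTACAATCTTCGGTTCGTCGCGTTTCATGACATAGCTAGTAAGCAAGCATGGTCTCGTTTGCCTAGGGCTGCATGTACCACTTCTTCGTGCTTCGTGAGACATGTCGTGTTAGAGGCGCTTGCCCAATATATCCCCGGTTCGGAAAAAGTTGTGCAGTCCATTTGTAAGCAGAAGGCGAGTACCGTG
>fam1_g2
CAAACCCAGAAGCGGACCATCGGAAATATGAATCGATGCGGCGGACACGGAGACCCAGACGAAGGTGCGAAAATTGCCGCCGAGACGCCTGTTCCACCCGGTTTATCAGTCGAACGTAAGGCATCTGTTTCCATTACGCTGCAACGAGCGGCGCTACGTTACGGACACTACCTTAACTTAGATGCCGGAACTCGGGATAATCGCTTAGTCCTAGGCTGCTCCCATCAGGAGATCGAACGGCCACTTATATGGTGGCCCGTTGAACTTAGAGACGTCCCTTCTCCGCCTAGACCGCGCCAACTACACTTCAACGTCAATGTATCATGCGGCCGCCGGGGGTCGACCCCCGTTTCATCGCGTCCTCCAATGACCCAGTGCCAGCGCCTGTCCCTAACCATATGCCACACGACGATGTGCTGGCGTGTCAGCCTCTCTAGTCATTCGAGGGAGCTTCTCATTGGTCTGAATGTACCCCTCCTGAGTGCTTGCCGCATGGTACAAAGTGCCGCACGTAAGCCCAGAAAAAGGCGATTTAACAACCCGACCGAGTACAAAGTGGTGACACACTTGACGGCTTTATCAGCATTACTTCAAATTGGGAATAGCACTTGGCTAGGCATTAGTAATATACAAGCAACTAACGCCGAATATAACCGAGAGAAACTCAACCTGGCTATTGAGGAAGCAGTGTCTCCGCGTGCTGATTCCGACAGGTACAATCTTCGATTCGTCGACTGTAATGACATAGCCAGTAAGCAAGCATTGTCGCGTTTCCCTAGAGCTGCATGGACCCCTTCTTCGTGTTTCGTGGGCCATGTCGTGTTAGAGCAGCTCGCTCAATATATCCCCGGATCGGAAAACGTTGTGCTGTCCATCTGCAAGCAGAAGGCGAGTACCATG
>fam1_g3
CAAACCCAGAAGCGGACCATCGGTAATATGAATCGATGCGGCGGACACGGAGACCCAGACGAAGGTGCGAAAATGGCCGCCGAGACTCCTGTTCCACCCGGTTTATCAGTCGAACGTAACGCATCTGTTTCCATTACGCTGCAACGAGCGGCGCTACGTTACGGACACTACCTTAAATTAGATGCCGGAACTCGGGATAATCGCTTAGTCCTAGGTTGCTCCCATCAGGAGATCGAACGGCCCCTTATATGGTGGCCCGTTGAACTTAGAGACGTCCCTTCTCCTCCAAGACCGCGCCAACTACACTTCAACGTCAATGTATCATGCGGCCGCCGGGGGTCAACCCCCGTTTCATCGCGTCCTCCAATGACCCAGTGCCAACGCCAGTCCCTAACCATATGCCACGCGACGATGTGCTGGCGTGTAAGCCTCTCTAGTCATTCGAGGGAGCTTCTCATTGGTCTGGATGTACCCCTCCTGAGTGCTTGCCGCATGGTACAAAGTGCCGCCCGTAAGCCCAGAAAAAGGCGATTTAACAACACGACCGAGTACAAAGTGGTGACACACTTGACGGCTTTATCAGCACTGCTTCAAATTGGGAATAGCACTTGGCTTGGCATTAGTAATATACAAGCAACCAACGTCGAGTATAACCGGGAGAAACTCAACCTGGCTATTGAGGAAGCAGTATCTCCGCGTGCCGATTCCGACAGGTACAATCTTCGATTCGTCGACTTCAATGACATAGCCAGTAAGCAAGCATTGTCGCGTTTCCCTAGAGCTGCATGGACCACTTCTTCGTGTTTCGTGGGCCATGTCGTTTTAGAGGAGCTTGCCCAATATATCCCCGGATCGGAAAACGTTGTGCAGTCCATCTGCAAGCAGAAGGCGAGTACCATG
>fam1_g4
CAAACCCAGAAGCGGACCATCGGTAATATGAATCGATGCGGCGGACACGGAGACCCAGACGAAGGTGCGAAAATAGCCGCCGAGACTCCTGTTCCACCCGGTTTATCAGTCGAACGTAGCGCATCTGTTTCCATTACGCTGCAACGAGCGGCGCTACGTTATGGACACTACCTTAATTTAGATCCCGGAACTCGGGATAATCGCTTAGTCCTAGGTTGCTCCCATCAGGAGATCGAACGGCCTCTGATATGGTGGCCCGTTGAACTTAAAGACGTCCCTTCTCCGCCTAGACCGCGCCAACTTCACTTCAACGTCAATGTGTCATGGGGCCGCCGGGGGTCGACCCCCGTTTCATCGCGTCCTCCAATGACCCAGTGCCAGCGCCAGTCCCTAACCATATGTCACGCGACGATGTGCTGGCGTGTAAGCCTCTCAAGTCATTCGAGGGAGCTTTTGACTGGTTTGAATGTCCCCCTCCCGAGTGCATGCCGCATGGTACAAAGTGCCGCCCGTAAGCCCAGAAAAAGGAGATTTAACAACCCGACCGAGTACAAAGTGGTGACACATTTAACGGCTTTATCAGCTCTACTTCAAATTGGGAATAGCACTTGGCTAGGCATTAGTAATATACAAGCAACTAACGCCGAGTACAACTGGGAGAAACTCAACCTAGCTATTGAGGAAGCAGTATCTCCGCGTGCTGATTCCGACAGGTACAATCTTCGATTCGTCGATTTTACTGACATGGCCAGTAAGCAAGCATTGTCTCGTTTCCCTAGAGCTGCATGTACCACTTCTTCGTGTTTCGTAGGCCATGTCGTGTTAGAGGAGCTTGCCCAATACATCCCCGGATCGGAAAACGTTGTGCAGTCCATCTGCAAGCAGAAGGCGAGTACCATG
>fam1_g5
CGAACGCGTAAGAGAACCATAGGTAATATCCACCGCTGTCGCGGACAGGGAGTCTCCACTGAAGGTGGCAAAATATCCCCAGAGACTCCTGTTCCACCTGGTCTATCTGTCGAATGTAACGCATCAAAACCGGTTACGCTACAACGAGCCGCGTTGCGTCTAGGGAACTTCCCTAATCTAGATCCTGGCACGCGTGATTATCGCCTAGTCTTCCGCCGCTCGTATCAGGAAATCGTACGGCCCGTTATACGTTCTTCAGTAGAACTTAAAGACGCTCCTTCCCCGCATCGACGGCGACAATTAGATTTTATCGTCAATGTATCATACGGGCTGCAAGGGACTACTCCCGTCTCATCTTGTCCCCCGATGACCCATTATCAGCGGCTGTTACCAACAGAATACGAAACCACAATGTGGTGGCGGGCCAGCCTCTCGAGTCATTCTAGGGAACTATCCATTGGTCTGAAAGTACCCTTGCTAAGTGCCTGCCGGATGGTACAGAGTGCTGCTCGAAGGCACATTAAAAGGCGTTCTATCAACCATAAAGGGTGCAAAGTAGTGACTCACCTAACAGCCCTGTCAGCATTGTATCAAATCGGGGATAGCACTAGGCCGAGCTTCAGCAATATTCAGGCCACCAAGGCCGAGTATTTCCGAGATGTACTCGACTTGTCAATAAAGGAGGCCGTTTCTTCCCGCGTGGATTCCAACCGGTCTAACTTACGTTTCGTCGAATTTGACGACACAGGCAGCCAGAAAGTCTTGTCACGTTTCACTAGGGCCGCGTGTACGACTTCTTCGTGCTTAGTAAGCCATGTCGTATTGGAGGAGCTTTCTCAATATATGCCCGTTTCCGAAAAAGCTGAGCAGTCTATATGTAAACAGACGGCCAACACCATG
>fam1_g6
CGAACGCGTAAGAGAACCATAGGTAATATTCACCGCTGTCGCGGACAGGGAGTCTCCACTGAAGGTGGTAAAATATCCCCAGAGACTCCTGTTCCACCTGGTCTATCTGTCGAATGTAACGCATCAAAACCGGTTACGCTACAACGAGCCGCGTTGCGTCTAGGGAACTTCCCTAATCTAGATCCTGGCACGCGTGATTATCGCCTAGTCTTCCGCCGCTCGTATCAGGAAATCGTACGGCCCGTTATACGTTCTTCAGTAGAACTTAAAGACGCTCCTTCCCCGCATCGACGGCGACAATTAGATTTTATCGTCAATGTATCATACGGGCTGCAAGGGACTACTCCCGTCTCATCTTGTCCCCCGATGACCCATTATCAGCGGCTGTTACCAACAGAATACGAAACCACAATGTGGTGGCGGGCCAGCCTCTCGAGTCATTCTAGGGAACTATCCATTGGTCTGAAAGTACCCTTGCTAAGTGCCTGCCGGATGGTACAGAGTGCTGCTCGAAGGCACATTAAAAGGCGTTCTATCAACCATAAAGGGTGCAAAGTAGTGACTCACCTAACAGCCCTGTCAGCATTGTATCAAATCGGGGATAGCACTAGGCCGAGCTTCAGCAATATTCAGGCCACCAAGGCCGAGTATTTCCGAGATGTACTCGACTTGTCAATAAAGGAGGCCGTTTCTTCCCGCGTGGATTCCAACCGGTCTAACTTACGTTTCGTCGAATTTGACGACACAGGCAGCCAGAAAGTCTTGTCACGTTTCACTAGGGCCGCGTGTACGACTTCTTCGTGCTTAGTAAGCCATGTCGTATTGGAAGAGCTTTCTCAATATATGCCCGTTTCCGAAAAAGCTGAGCAGTCTATATGTAAACAGACGGCCAATACCATG
>fam1_g7
CAAAACAGAAAGACCACCATCGGTAATATGAATCGTTGCGGAGGACAAGGAGACTCGTCGGAGGCGGACAAAATAGTCCCCGAGACTCCTGCACCGCCCGGTCTCTTCGCTGAAGGTAATGCGGTAATAACGATTACGCTACAACGGGCGGCGCTGCGACCCGGAAACTTCCCCAACCTAGAGCCTGGAACTCGTGATTACCGCCTAGTTTTTGGGCGCTCCCATCAGGAGATTGAACGACCTGTAATACGTTCCCCGGTCGAGCCTAAAGACGCTCCCTCGCCGCATAGGCCACGACAATTACATTTGAACGTAAATGTTTCATATGGGCGGCGGGGGACTACACTTGTCTCATCATGTCCTCCGATCACTCAATGTCAACGGCTGTCCCTAACTAAATGCGAAGCCACTATGTGGTGGCGGGCTAGCCTCCCTAGCCATTCGAGGGGTCTATCCATTGATCTGCTAGTACCCCTGCTGCGTGCTTGCCGCATGGTTCAGAGTGCCGCCCGCAAGCCAATTAAAGGACAATCTAATAATCCTAACGAGTGCAAGGTTGTGACCCACCTTACCGCCTTGTCGGCGCTTTTTCAAATCGGGAATAGCACCCCGCTAAGCTTTAGCAATACACAAGCCACTAAAGCGGAGCATAAGTGTGATATACTCGACTTAGCCATTAAGGAAGCCGTATCTCCCCGCGCTGATTCCAACAGGTGTAACCTACGATTCGTTGACTTCGATGATATTGCCAGCAAAGAAGTTTTGTCACGTTTCACTAAGGCAGCCTGTACGACTTCTTTGTGCTTGGTCAGCCATGTCGTATTGGAAGAGCTTGCTCAATATATGCCTGTGTCCGAAAAGGCTGAGCAGTCTCTATGTAAAAAGAAGGCAAGTACTATG
>fam1_g8
CAAACCAGAAAGAGAACCATCGGTGATATGAATCGATGCGGAGGGCAAGGAGCCTCCCCCGAGGGAGCCAAGATAGTCCCCGAAACCCCTGTTCCACCTGGTCTCTCTGTCGAGGGTTATGCGACAATATCCATTACGTTACAACGAGCTGCGTTGCGTCTCGGGAATATCCCGAATCTGGATCCTGGGACCCGGAATCATCGGTTAGTCTTTGGGCGCTCCCATAAAGAGATTGAACGTCCTGTTATACGTTCCCCTGTTGAACTCGGAGACGCTCCTTCTCCACATAGGCCTCGGCAATTACATTTCATAGTGGAGGTTTCATATGGGCGGCGGTGGACTACACTTGTTTCATCATGTCCTCCAATGACCCAATGTCAACGGCTGTCCCTAACTAAATGCGAGGCCACAATGTGGTGGCGGACTAATCTCTCAAGTCATTCCAGGGGTCCGTCCATTGATCTCCATGTGCCCTTGCTAAGTGCTCGCCGCATGGTACAGAGTGCCGCCCGTAAGCCCACGAAACGGCAATCGAACAATCCCAACGAGTGCAAGGTAGTAACCCACCTGACCGCACTGTCAGCCCTTTTTCAAATCGGGGATAGCAACCGGCTGAGTTTTAGCAATATACAAGCAACCAAAGTGAAGCTTAGCTGTGATATACTCGACTGGGCCATTAAGGAAGCACTATCTCCACGCACTGACTCTAACAGGTATAACCTACGCTTTGTCGACTTTGATGACCTAGCCAGTAAGGGAGTTTTGTCACGTTGGACTAGGGCAGCGTGTACGACATCTTCCTGCCTGGTGAGCCATGTCGTATTGGAGGAGCTTGCTCAATATATGCCCGTCTCCGAAAAAGCTGAGCAGTCTATATGTAAACAGAGAGCAAGTACTATG
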