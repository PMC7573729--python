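>fam2_g1
GCGTTGAGCCCCTTGACGTATTTTATATATTCGGCTTGGCCACTGGCGAAGCTTTACCTGCTGGGGCGGAGGTTCATCATCCACCCTACACTATTCTCAAATGCATCTAGCCACCGCGCCGACGGGGAGAGTCCAAGGAAGAAATGCCGAATCATGCACGTATATTGTGTCAACACGCAGAACGGGTGGTTTGGTCTTTGGAGTGCGCTCCGCCCCGTGCTCACCGCTTTTTATGGAATGGTTGGCACCCAAGCACGTGTGAAATTGGACGTCCGGCTTATGGTACACCGATCCGAGGTAAAGGTTCGAACGGGAGTTTATAGGTTGGATGCCTCGATGCAGAATTGGATAACCACTTATTGGGGATTGCTCAGCGTTGGTGGCTTGAGGACAAAGAACATATCGCCACATTTAGTTGAGCGAGTGAGAGCTAGGTATCACATCGGAACCCACGCACCCCCTGGTCGATACGAGCAAAGTGTCGAGGGAAGTCGGTCCTCCGCTAAGCCAACGCTAACTGGACAGGCGTACTTGAGATCCAAAACAATACCTCATCAGGCACAGGTTCCGCACACTCGCACACAGTCTCGCTGCCCAAAAGGCAAACGCAAAAAACCTGAATTGTGTCGCAATCCGCTTACTCGTCGTGTCTGGGGGTGCGGTTTACCCCTTTTTGTCTCATTTGCGCCACAGCTCCTTCTCGTAAAGCAACGGGTACGGGGATTATTCCGCGCCTTACTGACCAGCTTTAGACACAATCTGTTCCGCCTCTCTCAACGTACGCTTATTTCCGACACGAAGGGTCATAGTGTCAACGTTCTCACGCCGGATCTTCACCGGTCGCAGACTTACGTACATAAGGTAGTGCGGCTAAGTTCCCTCACGAAGGCACAAATAGAC
>fam2_g2
GCCGTGAGCCCCCTGACTTATTTTATATACTTGGCTTGGCCACTGGCGAAGCTATACTTGCTGGAGCGGAGGTTCATCACCCACCCTACACTAGTCTCAAATGCAGCCAGTCACCGCGCCGTCGGGGAGAGTTCGAGGAAGAAATACCGAATCATGCACATCTATTGTGTTAACACGCAGAACGGGTGGTTTGGTCTTTGGAGTTCGCTCCGCCCTGTGCTTACCGCATTTTACGGAATGGTTCGTACCCAAGCACGTGTGAAATTAGACGTTCGTCTTATGGTACACCGATCCGAGGTAAAAGTTCGCACAGGAGTTTGTAGGTTGGATGCGTTGATGCAGAACTGGATAACGACTTATTGGGGATTCCTTAGCGTTGGCGGCTTGAGGACAAAGAATAAATCGCTCCATTTAGTTGAGCGTGTGAGAGCTAGGTATCGTAGCGGAACGTACGCCCCCCCTGGCCGATACGAGCAAAGTGTCGAGGGAAGTCGGTCCTCCGCTAAGCCAACACTAACTGGACAGGCTGACCTGAGTTCCAAAACAATACCTCACCAGGCTCTAGTTCCGCACACCCGCACACAATCTCGCTACCGCAAAGGTAAACGCAATAAACCTGAATTGTGTCGCAGTCCCCTTACCCGTCGCGTCTGCGGGTACGGTTTACACCTCGCTGTTTCGTTCGCGCCACAGCTTCTTCTCGTAAAACAACGGGTACCGGGATTGTTCCGCGCCCTACTGACCAGCTCTAGATACAATCTGTCCCGCCTGTCTCAACGTACGCTTATTTCAGACACCAAGGTTCACAGTATTAACGTTCTCACGTCAGATCTACATCGGTCACAAACTTACGTACATAGAGTAGTGCGCCTAAGGTCTCTCACAAAGGCACAAATGAAC
>fam2_g3
GCAGGTCGACCGTCCATGTATTTCATACATTCTGGTTGGCCGACGGCGAAATTGTACTCCCTCGGACGTCGGTTCATCACGTACTCGACACTTATCTCCAGCGCATACCACCACCGCGCAGCAGGTGTGAACTCTGGTTACAAATACCAAGCCATGCACTGTTATCCTTTCAATACCCAAACCGGGTTCTTTGGTGGCTGTAGTGTCCTCTGCCCATTGCTTACAGAGTTTACCGGTAAAGTCCGCGCCCAAGCACTTGCAAAGTTAAACACGCGTCTGATGCAACTTACGTCTAAGATGAAGCTTCAAGCAGTATTGTTTAGGCAAGATGCATTACTACAGGATTGTATCGCTTCTTACCGGGGATTCCTTAACGCCGGTGTTTCTCGAACAATGAGTGTGCCTCCAGATCTGGTTAACTGGGAGAAAGCAAGCTACCTCGTGGGAACATACGCACATTCTGGTCGTTGCGGACGAGATGACAAGGGAAGTCAGCCCTCCGCGATACCGGCGCTTATAGCCCAGGTTTACGCTAGCTCCATGACAATATCGCAGCTGGCACAGGTCCCGCAGACACGCATACAGTCAGGCCACCATAAAGGAAAACAGAACAACCCTCGGTCGTGTCGAAATCCTTTAACCGGTCATGTAAGGAGGTACGGTTCTCCCGTTGCTCTGTCATTAGCGCCGCAGCTCCTCCTCGTGAAACAGCGTGTACCGGGTTTGTTTCGAGCGCTTGTCACGAGCTCATGCCATGATGGGCTACGACGATCTCAACGCACGCTAATTTCGTACGTAAAAAACCACAGCGTAAAGGCTCTTATGCCGGACCTCCACCGACTACAAACTTTCGTGAATAGACTTTTGCGACGGTGCTTTCTCATAAAACAGCGAATCGAC
>fam2_g4
GCCGGTCGACAGTTCATGTATTTCATACATTCAGGTTGGCCGACGGCGAAATTGTACTCCCTCGGACGTCGGTTTATTACATATCCTTCATTAATCTCCAGCGCATACCGCCACCGAGTAGCCGGTGTGAACCCAACGGACAAGTATCAAACCATGAACTGTTACCGTTTCAATACACAGAATGGGTTCTTTGGTCGTTGTAGTTTTCTCTGTCCTTTGCTTACAGAGTTCACTGGTAAAGTGCGCGGCCAAGCACTTGCAAAGTTAAACGCGCGCCTCATGGAACTTACATCGAAGATGAAGCTTCAAGCAGTAAGATATAGGCAGGATTCGTTAATACAAGACTGGAGAGCCTCTTATCGGGGGTTCCTTAACGCTGGTGTTTCGAGAACAGTGAGTGTACCTCCAAATCTTGTTAATAGGGAGAAAGCAAGCTACGTCGTAGGAACCTACGCCCTCTCTGGCCGCTGCGGACGGGATGACAAGGGGAGTCACCTCTCCGCCATACCTCCGCTTATAGCCCAAGTCTACACTAGCTCCATGACATTATCACACCTGGCACAAGTCCCGCACACGCGCATTCAATCTGGCCACCACAAAGGAAAACGCAACAACCCTGGGTTGTGTCGGAATCATCTAACCGGTCATGTATGGAGATACGGATCTCCCGTTGCGCTGTTATTCGCTCCGCAGCTCCTCCTCGTTAAACAGCGTGCACCGGGCCTGCTTCGAGGGCTCCTGCCCAGCTCAGGCCACGATCGACTCCGACGCTCTCAGAGGACCCTAATTTCTCACGTAAAAAACCACAGTGTAAAGGCCCTAATGCCAGACCTGCATCGATTACAAACATTCGTGAATAGACTAGTACGACGTTGCTTTCTCATTAAACAACTCATCGAC
>fam2_g5
GCCAGTCGACAGTTCATGTATTTCATACATTCAGGTTGGCCGACGGCGAAATTGTATTCCCTCGGACGCCGGTTTATTACGTATCCGACACTAATCTCCAGCGCATACCGCCACCGCGTAGCGGGTGTGAACCCAAGGGACAAGTATCAAACCATGAACTGCTACCGGTTCAATACCCAGAATGGGTTCTTTGGTCGTTGTAGTTTTCTCTGTCCTTTGCTTACAGAGTTCACCGGTAAAGTGCGCGGCCAAGCACTTGCAAAGTTAAACGCGCGCCTGATGGAACTTACATCGAAAATGAAGCTTCAAGCAGTAAGATATAGGCAAGATTCATTAATACAAGATTGGATAGCTTCTTACCGGGGGTTCCTTAACGCAGGTGTTTCGAGAACAATGAGTGTACCTCCAAATCTTGTTAATAGGGAGAAAGCAAGCTACGTCGTGGGAACCTACGCCCTCTCTGGTCGCTGCGGACGGGATGACAAGGGAAGTCAGCTCTCCGCCATACCTCCGCTCATAGCCCAAGTCGACACTTGCTCCATGATATTATCACACCTAGCACAAGTCCCGCACACGCGTATTCATTCTGGCCACCACAAAGGAAAACGCAACAACCCTGGGTTGTGTCGAAATCATATAACCGGTCATGTATGGAGGTACGGTTCTCCCGTTGCGGTGTCATTCGCTCCGCAGCTCCTCCTCGTTAAACAGCGTGTACCCGGCCTACTTCGAGCGCTCCTGCCCAGCTCAGGCCACGATCGACTCCGACGATCTCAGAGGACCCTAATTTCTCACGTAAAAAACCACAGTGTAAAGGCCCTAATGCCAGACCTGTATCGATTACAGACTTTCGTGAATAGATTAGTCCGACGTTGCTTCCTCATTAAACAACTCATCGAC
>fam2_g6
GCGAGACGGCCTTTTATTTTTTTCATACATTTTGCTTGGCCGCGGGCTAGACTGTATTCCATGGGACGACGGTTCATACCTTACCCCACCCTAATCTCCAGCGCCTACCGCCATCGAATAGACGGTTTGAGCTCCAGGGACAAGAACCAAACCATGCATTTCTATCGTTTCAATACAGAGACGGGCTTCTTTGCTCGATGCAGTTTTCTCTGTCCATTACTCACAGAGTTTTCAGGTACCGTGCGTGGCCACGCTGTGGTAAAGCTGAACGCGCGTCTGATGGATCTAACAAGGAAGATAAAGGTACAGGCCGTAATCTATAGACAAGATGCATTGATGCGAAATTGGATCGAATCTTACCGGGGATTTCTTAGTGCGGGCGTTTCGAGAACCACGATTGTGTCCCCGATCCTTACTAAACAAGTGAAAGCCAGACACATCATTGGGATGTACGCGCATTCTGGTCGCTGTGGCCGTGGTGACAAGGGAAGTCAGCCCTCCGCCACGCCCGCACTAATAGCACAGGCATACGCCGGGTCGACGACAATATCGCACCTAACACAGGTCCCGCATTCACGAATCCAGACAGGTCACCATAAAAGAAAACACAATAACCCCGAATTGGGTCCACATCCCCTGACAGGAAGCTTCTGGAGGTACGGTTCACCCGTTTCGCTGTCATTTGCTCCCCAGCTCCAACTAGTGAAACAGCGTGTACCGGGCCTGCGTGGTGTGCTACTGACTAGCTTATGCCATGGTCGTCTTGGGCTATCTCAACGCACGCTTATTTCTGACATAAAAGATCACAGGGTGAAGTCACTCATACCGGACCTGCAACGATCTCAGACATACGTGAATAGGGGTGTGCGACGATGCTTTCATATTAAACAACGAATCGAC
>fam2_g7
GCGAGACGGCCTTTTATGTACTTCATACATTTTGCTTGGCCAAGGGCTAGTCTGTATTCCATGCGACGACGGTTCATACCATACCCGACCCTGATCTCGAGCGCCTACCGTCATCGCATAGCCGGACTAAACTCAAGGGACAAGGACCAGACTATGCATTTGTATCGTTTCAATACAGAGACTGGCTTTTTTGCTAGGTTTGGTTTTCTCTGTCGATTGCTCACGGAGTTCTCCGGTACAGTGCGTGGCCAAGCTGTCGTAAAGTTAAACGCGCGTCTGATGGATCTTACATGGAAGATAAAAGTACAAGCGGTAATCTACGGACAAGATGCATTTATGCGAAATTGGATCGAATCTTACCGGGGATTTCTTAGCGCGGGCGTCTCGAGAACATCGATTGTGTCCCCGAACCTTGCTAACCGGGTGAATGCCAGAGACGTCATTGGGACGTACGCGCTATCTGGTCGCTGTGGACGTGGCGACAAAGGAAGTCAGCCCTCCGCAATACCCGCACTAATTGCTCAGGCATACGCCAGCTCGATGACAAGATCGCACCAAGCGCAGGTCCCGCATTCGAGGATTCAGTCGGGACACCATGATAAAAATCACAACAACCCCGAATTGTGTCCACATCCCCTAACAGGAAGCTTCTGGAGGTACGGTTCACCCGTTGCGCTATCATTTGCTCCTCAGCTCTTACTAGTGAAACAGCGTGTACCGGGCCTGCGTGGTGTGAAACTGACTAATTTATGCCATGGCCGTCTTCGATTATCTCAACGCACGCTTATTTCCGACGTAAAAGACCACAGTGTGAAGTCACTGATCCCGGACCTGCATCGCTCTCAAATATACGTGAAGAGAGGTGTGCAACGTTGCTTTCTTATTGAACAACGAATCGAC
>fam2_g8
GCGGGACGGCCATTCATATATTTCTTACAGTCAGCTTGGCCCCCGGCGAAATTGTATTCCCTCGGACGGCGATTCGTCACATACCCGACCTTGATCTCCAGTCTATATCGCCAGCGCGTTTCTGGTATCAACTCAAGAGACAAGTACCAGACGATGTACTTTAATCGCTTCAATACCTGGAAAGAGGTTTTTGGTCGCTGCAGTCTTCTCTGTCCTCTCCTCACAGAGTTCTCTGGTACCGTCCGCGGCCAGGCCCTCGTAAACCTGAATGCGCGACTAATGGAAATGACTTCGAAGATAAAGTTTCAAGCCGTAATACATACGCAAGATACCTTAATGCAAAATTGGATAGTTTCATACCGGGGATTTCTCACCACTTGTGTTTCGAGGACAACCAGTGCTTCCCCCAACCTTGTTAAAAGGGTGAAGGCCAGATACCGCATTGGCACACACGCGCTCTCTGGTCGCTGCGGCCGGGGCGCTAAGGGAAGTCAGCCCTCTGCCATACCCGCCCTTCTAGCCCAGGCGTACCCTAGCTCCATGACAATATCACACAAAGCGCAGGTCCCGCACACACGCATCCAATCTGGCCATCATAAAGGAAAACACAACAACCCTGAATCGTGCGGGAATCCCCTTACGGGTCACGTCTGGAGGTACGGTTCTCCTGCAGCGCTGTCATTCGCTCCGCAGCTTCTACTTGAGAAGCAGCGTGTGGCGGGCCTGTGTCGTGCGCTCTTGACGAGTTTATGCCATGATCGACGACGACTATCCCAGCGCACGCTTATTTCATACGTAAAAGTGCACAGTGTGCAGGCTTTCATGCCGGACTTGCATCTATCCCAAACTTACGTGAATAGAGGTCTTGGACGGTTCTTTATCATAAAACATAGAGTGGAT
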