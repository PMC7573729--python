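>fam3_g1
ACAGGCAATATCTACGAGTCCGTCTTGGAATCTTCCCGCTCCGTGTGGACTAGAGAGTCAAGGAAAGCAAGCGGACTTGGAGCCCTCAAAGCACGGTTTCTCACGAAAACGTATACCGCACACGGTGGTCTCCCAAGAGAGCTATACCAGGTTGAGAGCACATCACGGGGAGCTTACCAAACGGTTTCGAGATTACATATCCCTCGATATGGGTCCCATGACTGCCGAGGGGTACTAACGCTTGTACATTTCGGGTTATTTTCGCTTGATAGATACAGACAGGTATCGGTTGGCTTAACAGCTGAACCCGGGCACAATTCACCCCAATTGACCTTGAGTCCACGACTCCAGCGTAAAGTCTTCGCGATACAAGAACAGACTGGGTGCCCCCCGAAACCCCTCCCGACACGACAAGGGAACATTTTTACAACTATATGGACGGGCATCTTTCTCCGGGATACTGTTGGCAATCGTTACATATTGAAACTCGCCCGGGACAGGGATATGCCGGGGGGCAGACTTCATCGATTAAAGGGCACGCTTAGTTTGGTAATTGGGGCAGTCGGGTGGGTCGGAGAACTTCGTTTCAGGCTGCGAGCTTATCAGATCCGTATGTTGCTTCGAGACCCTGGTGGAATCGATCACCATAAGCGGTTTAAGTATATAAGGCTTCCGGAAAAGGAGTGGAATTGGATGTTGGACCTGCTTGACCTCTCAGAGTTATCAGCTTGCGGTCCACTATGTCAGATAAAATTTCGTAACCTCAGATCCATTTTACAGAGAGCCAGTGTCCTGGGAGTTTATAAGAACAGGGCAGCGATAGGGCATACCTGCTTCCTCATAGTACGGCAGGAAAGGTTGGTTGTTCGACGTCCCCCAGTAACATTTATCACACCAATC
>fam3_g2
ACAGGAAATACATACGAGTCCGTCTTGGAATCTTCCCGTTCTATGTGGACTAGAGAGTTGAGGAAAGCAAGCGGCCTTGGAGCCCTCAAAGCACGGTTTCTCACGAAAATGTATACTGCACACGGAGGACTCCCAAGAGAGCTATATCAAGTTGAGTGCACATCACGGGGAGCTTATCAAACGGTTTCGAGATTACATATACCTAGATATGGGCCCCATGACTGCCGTGGGGTACTAACGCCTGTACATCTCGAGTTATTTTCGCTAGACACATACAGACAGGCGTCGGTTGGCTTAACAGCTGAACCCGGACACCATTCACCCCAACTAACATCAAGCCCTCGGCTCCAGCGTAATGTCTTCGCGATACAGGAGCAGACCGGATGCCCCCCGAAACCCCTTCCGACACGACAAGGGAACATTTTTACAATTATATGGACGGGAATCTTTGTCCGGAATACTGTTGGCAATCGTTACATGTTGAAACTCGCTCGGGACAGGGACGCGCCCGGAGGTAGACTTCATCGATTAAAGGGCACGCTTAGTTTGGTCATTGCGGCAGTCGGATGGGTGGGAGAACTTCGTTTCAGGCTGCGAGCGTATCAGATCCGTATGTTGCTTCGAGACCCCGTTGGAATCGATAATCATAAGCGTTTTAAATATATAAGGCTTCCGGAAAAGGAGTGGGGTTGGATGTTGGACCTGCTTGACCACTCAGAGTTCTCAGCCTGCGGTCCTCTATGTCAGATAAAATCTCGTAACCTCAGATCCATTTTACAGAGAGCCAGTGTCCTGGAAGTTTATAAGAACAGGGCTGCAATAGGGCATACCTGCTTTCTTATGGTCCGGCAGAAAAGGTTAGATGTTCGACGTCCCCCCGTAACATTTATCACACCCATC
>fam3_g3
ACAGGCAATACATATGAGTCCGTCTTGGAATCCTCCCGCACCATGTGGACTAGAGAGTTGAGGATAGCCAGCGGGCTAGGAGCTCTCAAAACACGGTTTCTTCCGAAAATGTATACTGCACATGGAAGACTCCCTAGGGAGCGATATCAAGTTGAGAGCACATCGCGAGGAGCTTACCAGACGGTTTCGAGATTACATATCCCTCGTTATGGGCCACATGATTGCCGTGGGGTACTAACGCCTGTACATTTCCAGTTATTCTCGCTTGACACATACAGACAGGTTTCGGTAAGCTTAACAGCCGAACCCGGGCACAATTTACCGCAATTGACATCAAGTCTACGGCTCCAGCGTAAAGTCTTCGCGATACAGGTAAAGACTGGGTGCCCCCCGAAACCCGTCCCGACACGCCGAGGTAACATTTTTACCACCATCTGGACGGGCATCTTTGTGCGGGATACAGTTGGCAATCGTAACATATTGAAACTGGCTCGGGACTGGGATAGGCCCGGGGGACGACTTCACCGGTTAAAGGGCACGCTTAGTTTGGTTATTGCGGCAGTCGGGTGGGTCGGAGAACTTCGTTTCAGGCTACGAGCTTATCAGATCCGTATGTTGCTTCGAGACCCTGTTGGAATCGATAATCATATGCGGTTTAAATATATAAGGCTGCTGGAAAAGGAGTGGGATTGGATGTTGGACCTGCTTGATCTCTCAGAGTTCTCCGCGTGTGGGCCACTATGTCAGCTAAAATCTCGGAACCTCAGATCCATTTTACAAAGAGCCAGTGTCCTGGGAGTTTATAAGAGTAGGACAGCTATAGGGCATACCTGCTCTCTTATGGTTCGGCAGGAAAGGTTGGTGGTCCGACGTCCTCCAGTGACATTTATCACACCAATC
>fam3_g4
ACGGGCAATACATACGAGTCCGTCTTGGAATCCTCCCTCACTATGTGGACTAGCGACCTGACGACAGCGAGCAGCCTTGGGGCTCTCAAAGTACGTCTGCTTACGAAAATGTATACTGCCCTCGGAGGACTTCCCAGCGAACGATCTCAGGTAGAGAGCACATCACGAGGTGCTTACCAAACGGTTTCGGGATTACATATCCCTCGCTACGGGTCACATGATTGCCGCGGGGTACTAACGCCTGTACATTTTGATCTATTCTCGCTCGGCACATACCGACAGGTCTCTGTTAGTTTGACAGCAGAACCCGGACACAACTCAACGCAACTAACCTCTATCCTACGGCTACAGTATAAAGTGTTCGCGATACATGTACAAGCTGGATGCCCCCCCAAACCCCTACCGACACGCCAAGGGAACACTTTTACCACCATATGGACGGGTATGTTTGTGCGGGATACTGCTGGCAATCGTTATATATCGAAACTCGCTGGGGACAGGGGTACGCCCGGGGGACGACTCCACTCGTTAAACGGCACCCTAAGTCTGGTTATCACGGCGGTAGGGTGGGTCAGAGACCTTCGTCTTAGACTGCGAGCTTACCAGATCCGTATGTTGCATCGAGACCCTGTAGGGATCGATAATCTTAAGCGGTTCAAATATATAAGGCTTCTGGAAAAGGAATGGGATTGGATGTTGGACCTGCTCGATCTCTCAGAATTCTCCGCCTGCGGTCCTCTATGTCTACTAGAATCTCGTAACCTTAGGTCAATCCTACGACGAGCAAGCGTCCTCGGAGTTTATAAGAGTAGGGCTGCAATAGGGCACACCTGCTTTCTTACGGTACGCCAGGGAAGGTTGGTTGTTCGACGGCCCCCAGTAACATTTCTAACACCGATC
>fam3_g5
GCAAATGATCTTGACGCCATCTTTCTCTATGCTAATCGGCCAATGTGTGCTCAGGAGTGCGCTGAAGTGCACAGGCACCAGGCTACAACACCACGGATCCCCCATAATATATTAAACGGTGAGGGAAGACGCGTGAGAGGGCAGAATAAAGTAGAGAGAAGGGCGCGAGGGGCCTGCCGGAGAGTTACAAGGATTTTTATACCGCCTCGTGGATTACCTTCCTATCATGAGGGGTGGATTCTTAGACGTCACCGGCTTCTTCTATTTTGGTCTTACACCCAAGTCCTTGTAAGCCTAGAGGCGGAGGCGCCAAACAGTACACTGCCCCTAGCACAAAAACTCAGCCTTAAAACTAATAACATCGGACTCCACAAGCAAACAGGTTGCAACCCGCAATCGCCCCCGTCGCGACAGGCTAAAACTTATAAAATTACCTGCAAGGATCAATTTGACGGAGCGACTGTCGACAAACGGTATATATTGAAACATGATGGGGGTAAAGGTATCTCTGAGAACCCACGCTACCGTTTATGGGGTACTCTAGGTTTCTATCATAGGCCCGGCGGAGGGCTTAGAGGATTCAGTGTTAGATTACGATCTCTCCACATCGGTCTCTTGCCCCAGGCCTGCGCTGAAATCAATATTTATGAAACGGTTAAACGTACCTGTCTATCAGAAACGTCTCGGATGTGGCTGCTTGACTTTACGGACCTCTCAAAATTATACGCCTGCAGACATATGTCTCAACAGGATACTTGTTACCTCAGGGCAATTGCACAGAGAGTTCATGACTTAGCAGACCAGAGACACAGACTAGAGACGGGTCAAGGGTGTAGCAGGATGAGTCGGCAGGAAAGGTTCGTAGCGAATCGCCCCCTTATCACTCTAATCTCCCCGGAC
>fam3_g6
ACAGATGATCGTCACGCATTCTTTCTCGATACTAATGGTCCGTTATGTGCTCTAGAGTGCGATGGAGTCCACAGACTTCAAGCTACCACAGCACGGCTCCCCTATAATATGCCAAAAGCTGACGCAAGACCTGTAAGAGGTCAGTATAACGTTGAGAGAAAGCCACGAGGGGCCGGTCAGCGGGTTACAATGATCCTGATCCCGCTTTGTGGATTACATTCCCATCATGAGGGGTGGATTCTTACACGTCACCGGCTCTTTTTATTTAGGCCTTATAGACAGTTCCCTGTTCGCCTGGAGGCTGGGACGCCGAACAACATACTCCGCCTAACACAGAAGCCTCGTCTCAAAACTAACGACTTCGCCCTTCATGTTGAAACTGGGAGCAATCCACACTCTCCGCTATCACGTCAAGATAACATATCTACGATAACCTGCAAAAACCTATTTGGACGCGCCACCGTGAACAAGCGGTACATATTGAAACGCGGCGGGGGTAGAGGTATCTCTGAGAACCCACGGGACCGCTTATGGGGTACTCTCGGCTTGATTCATATGCCTGGCGGAGGGGTTAGAGAATCTAGTGTTGGGGTGCGATCCCCTCACATCGGCCTATTGCCTCAAACATATGCTGAAACCAATATTGGTGAGCAGGCTAAGCGTACTGGGCTCTCTAAATCTTGCAGGGTATGGCTTTTGGGCTTGACCGACGTATCAAAGCTCTACGTCTGCGGGCCTAGGTCGCAGCACGAACCCTGTTACCTGAGGACGATAGTACCGCGAAGTCATGACTTTGGGGATCGAAAGGACAGATCAGGAACGGGCCAGACGTGCTACCGGACGTGTCAACAAGAGAAATTTGTCGTGAGGCGTCCCCTCGTGACACTAATCTCCACGTTT
>fam3_g7
ACAGATGACCGTAGCGCAATCTTTCTCGATACTAATGGTCCGTTATGTGATATAGAGTGTGAAGTAGTTCACAGGCTTGAAGCTACCACAACACGCCTTCCCCTAAATATGCCATATGCTGACGAACGACCCGTGAGAGGTCACCATAACGTAGAGAGAAAGCCACGAGGGGCCTGTCAGAGGGTCACACGAATTCTCATCCCACTTTGTGGATTACCTTCCTACCATGAGGAGTGGATCCTCACACGTCACCGACTCTTTTTATTTTGGTCTTACCGACAATTCCCTGGTCGCCTGGAAGCTGGGACGCCCAACAGCATACTGCGCTTAACACAAAAGCTACTCCTCAAGACAAATGACTTCGCCTTATACGTAGAAACTGGGAGCAACCCACACTCGCCGCTGTCACGTCAAGATAACATATCTACAATTACTTGCATAAACCTAATTGGGCGGGCCACCGTCAACAGGCGATGCATATTGAAACGCGGCGGGGGTAGAGGTATTTCTGAAAACCCGCGTAACCGCTTATGGAGTACTCTTGGCTCGATTCATATGCCTGGCGGAGGGGTCAGAGAATCTAGTGTTGGGGTGCGATCCCCGCACATCAGCCTATTGCCTCAAACATATGCTGAAACCAATATTGATGAGCAGGCTGAGCGGTCTGGGCTCTCTCCGACGTGCAGGGTATGGCTGTTGGGATTGACAGACCTATCAAAGCTCTACGTCTGTGGGTCTGGGTCCCAGCAGGCACCCTTTTACCTGAGGACGGTCGTCCAGAGAGGCCATGACTTCGGAGACCGTAAGTATAGATTAGGAACGGGCCAGACGTGCCACCGGATGTGCCAACAAGACAGATTTGTTGTGAGTCGCCCCCCTGTGACACTAATCTCCATGATT
>fam3_g8
ACAGATGACCGTAGCGCAATCTTTCTCGATACTAATGGTCCGTTATGTGATATAGAGTGTGAAGTAGTTCACAGGCTTGAGGCTACCACAACACGCCTCCCCCTAAATATGCCATATGCTGACGAACGACCCGTGAGAGGTCACCATAACGTAGAGAGAAAGCCACGAGGGGCCTGCCAGAGGGTCACACGAATCCTCATCCCACTTTGTGGATTACCTTCCTACCATGAGGAGTGGATCCTTACACGTCACCGACTCTTTTTATTTTGGTCTTACCGACAATTCCCTGGTCGCCTGGAGGCTGGGACGCCCAACAGCATACTACGCTTAACACAAAAGCTACTACTAAAGACAAATGACCTTGCCTTATACGTAGAAACTGGGAGCAATCCACACTCTCCGCTGTCACGGCAAGATAACATCTCTACAATTACTTGCATAAACCTAATTGGGCGGGCCACAGTCAATAGGCGATGCATATTGAAACGCGGCGGGGGTAGAGGTATTTCTGAAAACCCGCGTAACCGCTTATGGAGTACTCTTGGCTCCATTCATATGCCTGGCGGAGGGGTTAGAGAATCTAGTGTTGGGGTGCGATCCCCGCACATCAGCCTATTGCCTCAAACATATGCTGAAACCAATATTGATGAGCAGGCTAAGCGGTCTGGGCTCTCTCCGACGTGCAGGGTATGGCTGTTGGGATTGACAGACCTATCAAAACTCTACGTCTGTGGGTCTGGGTTCCAGCAGGCACCCTTTTACCTGAGGACGGTCGTCCAGAGAGGCCATGACTTCGAAGACCGCAAGGATAGATTAGGAACGGGCCAGACGTGCCACCGGATGTGCCAACAAGACAGATTTGTTGTGAGTCGCCCCCCTGTGACACCAATCTCGATGATT
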